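"""Distance-based analysis of molecular variance (AMOVA) with Phi-statistics.

Partitions the variance implicit in a matrix of pairwise genetic distances
across a nested sampling hierarchy — among oceanic basins, among populations
within basins, and within populations — following the Excoffier-type
sums-of-squares decomposition with unequal-size expected-mean-square
coefficients. Significance of the Phi-statistics is assessed by permutation.

The model object follows the fit/results convention: build an
:class:`Amova` from a distance matrix and labels (or directly from an
:class:`~ribovar.io.AnnotatedDataset`), call :meth:`Amova.fit`, and read
components, Phi-statistics, permutation p-values and a printable summary
from the returned :class:`AmovaResults`.

Distance semantics: the decomposition operates on squared Euclidean
surrogates delta^2. With ``delta="count"`` (default) the raw count of
pairwise nucleotide differences is used directly as delta^2 — the
convention of the standard haplotype-network/AMOVA tools; with
``delta="squared-count"`` the counts are squared first.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ribovar.io import AnnotatedDataset
from ribovar.popgen import SiteMask, build_site_mask, pairwise_differences

Delta = Literal["count", "squared-count"]
Level = Literal["nested", "populations-only"]


# ---------------------------------------------------------------------------
# core decomposition on integer-coded label vectors
# ---------------------------------------------------------------------------

def _block_sum(sq: np.ndarray, idx: np.ndarray) -> float:
    """Sum of delta^2 over unordered pairs within one index block."""
    return float(sq[np.ix_(idx, idx)].sum() / 2.0)


def _nested_decomposition(
    sq: np.ndarray, groups: np.ndarray, subgroups: np.ndarray
) -> dict:
    """SS, df and variance components for the two-level nested design.

    ``groups`` and ``subgroups`` are integer-coded label vectors (subgroups
    globally unique, nested in groups).
    """
    N = sq.shape[0]
    group_ids = np.unique(groups)
    sub_ids = np.unique(subgroups)
    G, P = len(group_ids), len(sub_ids)
    if G < 2:
        raise ValueError(
            "nested AMOVA needs >= 2 groups (basins); "
            "run a populations-only AMOVA instead"
        )
    if P == G:
        raise ValueError(
            "every basin holds a single population, so the among-populations-"
            "within-basins stratum has zero degrees of freedom; run a "
            "one-level (populations-only) AMOVA instead"
        )

    ss_total = float(sq.sum() / (2.0 * N))
    ss_wp = 0.0
    sub_sizes = {}
    for s in sub_ids:
        idx = np.flatnonzero(subgroups == s)
        sub_sizes[s] = len(idx)
        ss_wp += _block_sum(sq, idx) / len(idx)
    ss_within_groups_total = 0.0
    group_sizes = {}
    sum_np2_over_Ng = 0.0  # sum_g (sum_{p in g} n_p^2) / N_g
    for g in group_ids:
        idx = np.flatnonzero(groups == g)
        group_sizes[g] = len(idx)
        ss_within_groups_total += _block_sum(sq, idx) / len(idx)
        subs_in_g = np.unique(subgroups[idx])
        sum_np2_over_Ng += sum(sub_sizes[s] ** 2 for s in subs_in_g) / len(idx)
    ss_ap = ss_within_groups_total - ss_wp
    ss_ag = ss_total - ss_within_groups_total

    df_a, df_b, df_c = G - 1, P - G, N - P
    sum_np2 = sum(v**2 for v in sub_sizes.values())
    sum_Ng2 = sum(v**2 for v in group_sizes.values())
    n1 = (N - sum_np2_over_Ng) / df_b
    n2 = (sum_np2_over_Ng - sum_np2 / N) / df_a
    n3 = (N - sum_Ng2 / N) / df_a

    ms_c = ss_wp / df_c
    ms_b = ss_ap / df_b
    ms_a = ss_ag / df_a
    sigma_c = ms_c
    sigma_b = (ms_b - sigma_c) / n1
    sigma_a = (ms_a - sigma_c - n2 * sigma_b) / n3
    return {
        "df": {"among_groups": df_a, "among_subgroups": df_b, "within": df_c},
        "ss": {"among_groups": ss_ag, "among_subgroups": ss_ap, "within": ss_wp},
        "sigma2": {
            "among_groups": sigma_a,
            "among_subgroups": sigma_b,
            "within": sigma_c,
        },
    }


def _one_level_decomposition(sq: np.ndarray, subgroups: np.ndarray) -> dict:
    """SS, df and variance components for the one-level (populations) design."""
    N = sq.shape[0]
    sub_ids = np.unique(subgroups)
    P = len(sub_ids)
    if P < 2:
        raise ValueError("one-level AMOVA needs >= 2 populations")
    ss_total = float(sq.sum() / (2.0 * N))
    ss_w = 0.0
    sizes = []
    for s in sub_ids:
        idx = np.flatnonzero(subgroups == s)
        sizes.append(len(idx))
        ss_w += _block_sum(sq, idx) / len(idx)
    ss_a = ss_total - ss_w
    df_a, df_w = P - 1, N - P
    n_prime = (N - sum(v**2 for v in sizes) / N) / df_a
    sigma_w = ss_w / df_w
    sigma_a = (ss_a / df_a - sigma_w) / n_prime
    return {
        "df": {"among_subgroups": df_a, "within": df_w},
        "ss": {"among_subgroups": ss_a, "within": ss_w},
        "sigma2": {"among_subgroups": sigma_a, "within": sigma_w},
    }


def _phi_from_sigma(sigma2: dict) -> dict:
    total = sum(sigma2.values())
    phi: dict[str, float | None] = {}
    if total <= 0:
        return {"phi_st": None, "phi_sc": None, "phi_ct": None}
    if "among_groups" in sigma2:
        a, b, c = (
            sigma2["among_groups"],
            sigma2["among_subgroups"],
            sigma2["within"],
        )
        phi["phi_st"] = (a + b) / total
        phi["phi_sc"] = b / (b + c) if (b + c) > 0 else None
        phi["phi_ct"] = a / total
    else:
        a = sigma2["among_subgroups"]
        phi["phi_st"] = a / total
        phi["phi_sc"] = None
        phi["phi_ct"] = None
    return phi


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class Amova:
    """Nested (or one-level) AMOVA model over a pairwise distance matrix.

    Parameters
    ----------
    distances
        Symmetric pairwise distances with a zero diagonal (typically
        absolute nucleotide-difference counts).
    populations
        Population (subgroup) label per sequence, aligned with
        ``distances.ids``.
    basins
        Basin (group) label per sequence; required for ``level="nested"``.
    level
        ``"nested"`` (among basins / among populations within basins /
        within populations) or ``"populations-only"``.
    delta
        ``"count"`` treats the supplied distance as delta^2 directly;
        ``"squared-count"`` squares it first.
    """

    def __init__(
        self,
        distances: DistanceMatrix,
        populations: Sequence[str],
        basins: Sequence[str] | None = None,
        level: Level = "nested",
        delta: Delta = "count",
    ) -> None:
        self.distances = distances
        n = len(distances.ids)
        if len(populations) != n:
            raise ValueError("one population label required per sequence")
        self.populations = np.asarray(populations, dtype=object)
        if level == "nested":
            if basins is None:
                raise ValueError("nested AMOVA requires basin labels")
            if len(basins) != n:
                raise ValueError("one basin label required per sequence")
            self.basins = np.asarray(basins, dtype=object)
            # populations must nest in basins
            for pop in np.unique(self.populations):
                b = np.unique(self.basins[self.populations == pop])
                if len(b) > 1:
                    raise ValueError(
                        f"population {pop!r} spans multiple basins: {list(b)}"
                    )
        else:
            self.basins = None
        self.level = level
        self.delta = delta
        d = distances.data.astype(float)
        self._sq = d if delta == "count" else d**2

    @classmethod
    def from_dataset(
        cls,
        dataset: AnnotatedDataset,
        mask: SiteMask | None = None,
        level: Level = "nested",
        delta: Delta = "count",
    ) -> "Amova":
        """Build the model from an annotated dataset.

        Distances are absolute pairwise nucleotide-difference counts on the
        dataset's (complete-deletion) site mask; hierarchy labels come from
        the metadata.
        """
        if mask is None:
            mask = build_site_mask(dataset)
        d = pairwise_differences(dataset, mask)
        pops = [m.population for m in dataset.metadata]
        basins = [m.basin for m in dataset.metadata]
        return cls(d, pops, basins=basins, level=level, delta=delta)

    # -- fitting ----------------------------------------------------------
    def _decompose(self, pops: np.ndarray, basins: np.ndarray | None) -> dict:
        if self.level == "nested":
            return _nested_decomposition(self._sq, basins, pops)
        return _one_level_decomposition(self._sq, pops)

    def fit(
        self, n_permutations: int = 1000, seed: int | None = None
    ) -> "AmovaResults":
        """Estimate components and Phi-statistics; permute for significance.

        Set ``n_permutations=0`` to skip the permutation tests (components
        only). With permutations, ``seed`` is required for reproducibility
        and p = (#{Phi_perm >= Phi_obs} + 1) / (n_permutations + 1).
        """
        pops, _ = pd.factorize(self.populations)
        basins = None
        if self.level == "nested":
            basins, _ = pd.factorize(self.basins)
        decomp = self._decompose(pops, basins)
        phi = _phi_from_sigma(decomp["sigma2"])
        pvalues: dict[str, float | None] = {}
        if n_permutations:
            if n_permutations < 99:
                raise ValueError("use at least 99 permutations")
            if seed is None:
                raise ValueError("a seed is required for permutation tests")
            pvalues = self._permute(pops, basins, phi, n_permutations, seed)
        return AmovaResults(
            model=self,
            df=decomp["df"],
            ss=decomp["ss"],
            sigma2=decomp["sigma2"],
            phi=phi,
            pvalues=pvalues,
            n_permutations=n_permutations,
            seed=seed,
        )

    def _permute(
        self,
        pops: np.ndarray,
        basins: np.ndarray | None,
        phi_obs: dict,
        n_perm: int,
        seed: int,
    ) -> dict:
        """Permutation nulls for each defined Phi-statistic.

        Phi_ST: individuals permuted among populations (basin structure
        follows the population labels). Phi_SC: individuals permuted among
        populations within their basin. Phi_CT: whole populations permuted
        among basins.
        """
        rng = np.random.default_rng(seed)
        counts = {k: 0 for k, v in phi_obs.items() if v is not None}
        if not counts:
            return {k: None for k in phi_obs}
        N = len(pops)

        pop_to_basin = None
        pop_ids = np.unique(pops)
        if basins is not None:
            pop_to_basin = np.array(
                [basins[pops == p][0] for p in pop_ids]
            )

        for _ in range(n_perm):
            if "phi_st" in counts:
                perm = rng.permutation(N)
                p_pops = pops[perm]
                p_basins = basins[perm] if basins is not None else None
                try:
                    d = self._decompose(p_pops, p_basins)
                    val = _phi_from_sigma(d["sigma2"])["phi_st"]
                    if val is not None and val >= phi_obs["phi_st"] - 1e-12:
                        counts["phi_st"] += 1
                except ValueError:
                    counts["phi_st"] += 1  # degenerate shuffle counted extreme
            if "phi_sc" in counts:
                p_pops = pops.copy()
                for b in np.unique(basins):
                    idx = np.flatnonzero(basins == b)
                    p_pops[idx] = pops[idx][rng.permutation(len(idx))]
                d = self._decompose(p_pops, basins)
                val = _phi_from_sigma(d["sigma2"])["phi_sc"]
                if val is not None and val >= phi_obs["phi_sc"] - 1e-12:
                    counts["phi_sc"] += 1
            if "phi_ct" in counts:
                shuffled = pop_to_basin[rng.permutation(len(pop_ids))]
                basin_of_pop = dict(zip(pop_ids, shuffled))
                p_basins = np.array([basin_of_pop[p] for p in pops])
                try:
                    d = self._decompose(pops, p_basins)
                    val = _phi_from_sigma(d["sigma2"])["phi_ct"]
                    if val is not None and val >= phi_obs["phi_ct"] - 1e-12:
                        counts["phi_ct"] += 1
                except ValueError:
                    counts["phi_ct"] += 1
        out: dict[str, float | None] = {}
        for k, v in phi_obs.items():
            out[k] = (counts[k] + 1) / (n_perm + 1) if v is not None else None
        return out


_STRATUM_LABELS = {
    "among_groups": "Among oceanic basins",
    "among_subgroups": "Among populations",
    "within": "Within populations",
}


@dataclass
class AmovaResults:
    """Fitted AMOVA: SS decomposition, components, Phi-statistics, p-values."""

    model: Amova
    df: dict[str, int]
    ss: dict[str, float]
    sigma2: dict[str, float]
    phi: dict[str, float | None]
    pvalues: dict[str, float | None]
    n_permutations: int
    seed: int | None

    @property
    def sigma2_total(self) -> float:
        return sum(self.sigma2.values())

    @property
    def percent_variation(self) -> dict[str, float | None]:
        """Percent of total variance per stratum, unclamped (may be negative).

        Undefined (all None) when the total variance is not positive.
        """
        total = self.sigma2_total
        if total <= 0:
            return {k: None for k in self.sigma2}
        return {k: 100.0 * v / total for k, v in self.sigma2.items()}

    @property
    def percent_variation_clamped(self) -> dict[str, float | None]:
        """Percent variation with negative components displayed as 0.

        A negative variance component is an artifact of the
        method-of-moments solve and is conventionally read as 0%.
        """
        pct = self.percent_variation
        return {
            k: (max(v, 0.0) if v is not None else None) for k, v in pct.items()
        }

    @property
    def phi_st(self) -> float | None:
        return self.phi["phi_st"]

    @property
    def phi_sc(self) -> float | None:
        return self.phi.get("phi_sc")

    @property
    def phi_ct(self) -> float | None:
        return self.phi.get("phi_ct")

    def summary(self) -> pd.DataFrame:
        """Table-style layout: stratum, Df, SS, variance component, %, Phi, p."""
        strata = list(self.df)
        pct = self.percent_variation
        rows = []
        for s in strata:
            rows.append(
                {
                    "stratum": _STRATUM_LABELS[s],
                    "df": self.df[s],
                    "SS": self.ss[s],
                    "variance_component": self.sigma2[s],
                    "percent_variation": pct[s],
                }
            )
        rows.append(
            {
                "stratum": "Total",
                "df": sum(self.df.values()),
                "SS": sum(self.ss.values()),
                "variance_component": self.sigma2_total,
                "percent_variation": None
                if pct[strata[0]] is None
                else sum(pct[s] for s in strata),
            }
        )
        out = pd.DataFrame(rows)
        out["phi"] = None
        out["phi_p"] = None
        phi_by_stratum = {
            "among_groups": ("phi_ct", self.phi_ct),
            "among_subgroups": ("phi_sc", self.phi_sc)
            if "among_groups" in self.df
            else ("phi_st", self.phi_st),
            "within": ("phi_st", self.phi_st),
        }
        for i, s in enumerate(strata):
            name, val = phi_by_stratum[s]
            out.loc[i, "phi"] = val
            out.loc[i, "phi_p"] = self.pvalues.get(name)
        return out

    def __str__(self) -> str:  # pragma: no cover - convenience printing
        head = (
            f"AMOVA ({self.model.level}, delta={self.model.delta}, "
            f"n={len(self.model.distances.ids)}, "
            f"permutations={self.n_permutations})"
        )
        return head + "\n" + self.summary().to_string(index=False)
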