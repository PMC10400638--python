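"""Beta-dispersion analysis of intra-genomic variability.

The intra-genomic variability of each specimen is summarised as the
distance-to-centroid of its clone sequences in principal-coordinate space:
pairwise (patristic) distances are square-root transformed, ordinated by
PCoA with Gower double-centering, and each sequence's distance to its
specimen centroid is computed with the subtractive squared-distance
convention on negative-eigenvalue axes (the behaviour of the classical
multivariate-dispersion method). The resulting per-sequence scores z are
then tested with a sequential (Type I) ANOVA over design factors and
pairwise rank-sum tests with step-down multiple-testing adjustment.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import dendropy
import numpy as np
import pandas as pd
from scipy import stats
from skbio import DistanceMatrix
from statsmodels.stats.multitest import multipletests

from ribovar.io import SampleMetadata
from ribovar.trees import patristic_matrix

logger = logging.getLogger(__name__)

_EIG_TOL = 1e-10


@dataclass(frozen=True)
class OrdinationResult:
    """Full-spectrum PCoA: signed eigenvalues and split coordinate blocks.

    ``coords_pos``/``coords_neg`` are the coordinates on positive- and
    negative-eigenvalue axes (each axis scaled by sqrt(|eigenvalue|));
    squared inter-point distances in the original (transformed) matrix are
    recovered as squared Euclidean distance on the positive block minus
    that on the negative block.
    """

    ids: tuple[str, ...]
    eigenvalues: np.ndarray  # descending, signed
    coords_pos: np.ndarray  # (n, n_pos)
    coords_neg: np.ndarray  # (n, n_neg)


def pcoa(
    distances: DistanceMatrix, transform: Literal["sqrt", None] = "sqrt"
) -> OrdinationResult:
    """Principal coordinate analysis of (optionally sqrt-transformed) distances.

    Applies Gower double-centering to -1/2 D^2 and a full symmetric
    eigendecomposition, keeping negative-eigenvalue axes separately rather
    than discarding them.
    """
    d = distances.data.astype(float)
    if transform == "sqrt":
        d = np.sqrt(d)
    elif transform is not None:
        raise ValueError(f"unknown transform {transform!r}")
    n = d.shape[0]
    a = -0.5 * d**2
    j = np.eye(n) - np.ones((n, n)) / n
    g = j @ a @ j
    g = (g + g.T) / 2.0
    eigval, eigvec = np.linalg.eigh(g)
    order = np.argsort(eigval)[::-1]
    eigval = eigval[order]
    eigvec = eigvec[:, order]
    pos = eigval > _EIG_TOL
    neg = eigval < -_EIG_TOL
    coords_pos = eigvec[:, pos] * np.sqrt(eigval[pos])
    coords_neg = eigvec[:, neg] * np.sqrt(-eigval[neg])
    return OrdinationResult(
        ids=tuple(distances.ids),
        eigenvalues=eigval,
        coords_pos=coords_pos,
        coords_neg=coords_neg,
    )


def distance_to_centroid(
    ordination: OrdinationResult, groups: Sequence[str]
) -> pd.DataFrame:
    """Distance of each point to its group centroid in PCoA space.

    Squared distance = squared Euclidean distance on positive axes MINUS
    that on negative axes; a (rare) negative squared value is floored at 0
    with a logged warning. Singleton groups get z = 0.
    """
    groups = np.asarray(groups, dtype=object)
    if len(groups) != len(ordination.ids):
        raise ValueError("one group label required per ordinated sequence")
    z = np.zeros(len(groups))
    floored = 0
    for g in np.unique(groups):
        idx = np.flatnonzero(groups == g)
        cp = ordination.coords_pos[idx].mean(axis=0)
        cn = ordination.coords_neg[idx].mean(axis=0)
        sq = ((ordination.coords_pos[idx] - cp) ** 2).sum(axis=1) - (
            (ordination.coords_neg[idx] - cn) ** 2
        ).sum(axis=1)
        neg = sq < 0
        if neg.any():
            floored += int(neg.sum())
            sq = np.where(neg, 0.0, sq)
        z[idx] = np.sqrt(sq)
    if floored:
        logger.warning(
            "floored %d negative squared distances-to-centroid at 0", floored
        )
    return pd.DataFrame({"sequence_id": list(ordination.ids), "group": groups, "z": z})


def _dummies(values: np.ndarray) -> np.ndarray:
    levels = pd.unique(values)
    return (values[:, None] == levels[None, :]).astype(float)


def sequential_anova(
    scores: pd.DataFrame, factors: Sequence[str], response: str = "z"
) -> pd.DataFrame:
    """Sequential (Type I) ANOVA of the dispersion scores.

    Factors are entered in the given order; each row reports the degrees of
    freedom, sum of squares and R^2 = SS / SS_total of that factor's
    increment, followed by a residual row. R^2 across factors plus the
    residual sums to 1.
    """
    z = scores[response].to_numpy(float)
    n = len(z)
    ss_total = float(((z - z.mean()) ** 2).sum())
    if ss_total == 0:
        raise ValueError("response is constant; ANOVA undefined")
    X = np.ones((n, 1))
    rank = 1
    rss_prev = ss_total
    rows = []
    for factor in factors:
        vals = scores[factor].to_numpy(object)
        if len(pd.unique(vals)) < 2:
            raise ValueError(f"factor {factor!r} is constant across all rows")
        X = np.hstack([X, _dummies(vals)])
        beta, _, new_rank, _ = np.linalg.lstsq(X, z, rcond=None)
        rss = float(((z - X @ beta) ** 2).sum())
        rows.append(
            {
                "factor": factor,
                "df": int(new_rank - rank),
                "SS": rss_prev - rss,
                "R2": (rss_prev - rss) / ss_total,
            }
        )
        rank, rss_prev = new_rank, rss
    rows.append(
        {
            "factor": "Residuals",
            "df": int(n - rank),
            "SS": rss_prev,
            "R2": rss_prev / ss_total,
        }
    )
    return pd.DataFrame(rows)


def _tier(p: float) -> str:
    if p < 1e-6:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def pairwise_wilcoxon(
    scores: pd.DataFrame,
    factor: str,
    adjustment: Literal["holm", "bonferroni", "none"] = "holm",
    response: str = "z",
) -> pd.DataFrame:
    """Two-sided rank-sum tests between every pair of factor levels.

    Uses the exact null distribution when both groups have <= 25
    observations and there are no ties, otherwise the normal approximation
    with tie and continuity corrections. Raw p-values are adjusted across
    pairs (Holm step-down by default). Significance tiers: ``*`` for
    adjusted p < 0.05, ``**`` for adjusted p < 1e-6.
    """
    levels = list(pd.unique(scores[factor]))
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} has fewer than 2 levels")
    samples = {
        lev: scores.loc[scores[factor] == lev, response].to_numpy(float)
        for lev in levels
    }
    for lev, x in samples.items():
        if x.size == 0:
            raise ValueError(f"factor level {lev!r} has zero observations")
    rows = []
    for g1, g2 in itertools.combinations(levels, 2):
        x, y = samples[g1], samples[g2]
        no_ties = len(np.unique(np.concatenate([x, y]))) == len(x) + len(y)
        method = "exact" if (len(x) <= 25 and len(y) <= 25 and no_ties) else "asymptotic"
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
        rows.append(
            {
                "group1": g1,
                "group2": g2,
                "W": float(res.statistic),
                "p": float(res.pvalue),
                "method": method,
            }
        )
    out = pd.DataFrame(rows)
    if adjustment == "none":
        out["p_adj"] = out["p"]
    else:
        out["p_adj"] = multipletests(out["p"].to_numpy(), method=adjustment)[1]
    out["significance"] = [_tier(p) for p in out["p_adj"]]
    out.attrs["adjustment"] = adjustment
    return out


# ---------------------------------------------------------------------------
# model / results
# ---------------------------------------------------------------------------

class BetaDispersion:
    """Beta-dispersion model of intra-genomic variability.

    Ordinates the square-root-transformed pairwise (patristic) distances of
    all sequences once, takes the distance-to-centroid of every sequence
    within its *specimen* group, and exposes ANOVA / pairwise rank-sum
    tests of those scores against higher-level factors (basin, invasion
    status, population).

    Parameters
    ----------
    distances
        Pairwise distances between sequences (patristic lengths or
        nucleotide-difference counts).
    metadata
        One :class:`~ribovar.io.SampleMetadata` per sequence id in
        ``distances``.
    intra_only
        With the default ``False``, scores come from the single ordination
        of the full matrix (the behaviour of the named dispersion method).
        With ``True``, each specimen's scores are computed from its own
        sequences' distances alone (closed-form distance-to-centroid on the
        specimen submatrix), ignoring between-specimen geometry.
    """

    def __init__(
        self,
        distances: DistanceMatrix,
        metadata: Sequence[SampleMetadata],
        transform: Literal["sqrt", None] = "sqrt",
        intra_only: bool = False,
    ) -> None:
        meta = {m.sequence_id: m for m in metadata}
        missing = sorted(set(distances.ids) - set(meta))
        extra = sorted(set(meta) - set(distances.ids))
        if missing or extra:
            raise ValueError(
                f"metadata mismatch; missing: {missing}; unmatched: {extra}"
            )
        self.distances = distances
        self.metadata = [meta[i] for i in distances.ids]
        self.transform = transform
        self.intra_only = intra_only

    @classmethod
    def from_tree(
        cls,
        tree: dendropy.Tree,
        metadata: Sequence[SampleMetadata],
        **kwargs,
    ) -> "BetaDispersion":
        """Build from a phylogeny: distances are patristic path sums."""
        return cls(patristic_matrix(tree), metadata, **kwargs)

    def fit(self) -> "BetaDispersionResults":
        specimens = [m.specimen_id for m in self.metadata]
        if self.intra_only:
            scores = self._intra_only_scores(specimens)
            ordination = None
        else:
            ordination = pcoa(self.distances, transform=self.transform)
            scores = distance_to_centroid(ordination, specimens)
        scores = scores.rename(columns={"group": "specimen_id"})
        for col in ("population", "basin", "invasion_status", "genotype"):
            scores[col] = [getattr(m, col) for m in self.metadata]
        return BetaDispersionResults(
            model=self, ordination=ordination, scores=scores
        )

    def _intra_only_scores(self, specimens: list[str]) -> pd.DataFrame:
        """Closed-form per-specimen distance-to-centroid on the submatrix.

        For a group of k points with squared distances delta^2, the squared
        distance of point i to the group centroid is
        mean_j delta^2_ij - (1/k^2) * sum_{j<l} delta^2_jl.
        """
        d = self.distances.data.astype(float)
        if self.transform == "sqrt":
            d = np.sqrt(d)
        sq = d**2
        spec = np.asarray(specimens, dtype=object)
        z = np.zeros(len(spec))
        floored = 0
        for g in np.unique(spec):
            idx = np.flatnonzero(spec == g)
            k = len(idx)
            block = sq[np.ix_(idx, idx)]
            zi = block.mean(axis=1) - block.sum() / (2 * k * k)
            neg = zi < 0
            floored += int(neg.sum())
            z[idx] = np.sqrt(np.where(neg, 0.0, zi))
        if floored:
            logger.warning("floored %d negative squared distances at 0", floored)
        return pd.DataFrame(
            {"sequence_id": list(self.distances.ids), "group": spec, "z": z}
        )


@dataclass
class BetaDispersionResults:
    """Per-sequence dispersion scores plus factor tests."""

    model: BetaDispersion
    ordination: OrdinationResult | None
    scores: pd.DataFrame

    def anova(self, factors: Sequence[str] = ("basin", "population", "specimen_id")) -> pd.DataFrame:
        """Sequential ANOVA of z over the given factor order."""
        return sequential_anova(self.scores, factors)

    def pairwise(
        self,
        factor: str = "basin",
        adjustment: Literal["holm", "bonferroni", "none"] = "holm",
        unit: Literal["specimen", "sequence"] = "specimen",
    ) -> pd.DataFrame:
        """Pairwise rank-sum tests of z between levels of one factor.

        With the default ``unit="specimen"`` each specimen contributes its
        mean score once (clones of one genome share a centroid, so
        sequence-level values are pseudo-replicated and anticonservative);
        ``unit="sequence"`` tests the raw per-sequence scores.
        """
        if unit == "specimen":
            data = (
                self.scores.groupby("specimen_id", sort=True)
                .agg({"z": "mean", factor: "first"})
                .reset_index()
            )
        elif unit == "sequence":
            data = self.scores
        else:
            raise ValueError(f"unknown test unit {unit!r}")
        return pairwise_wilcoxon(data, factor, adjustment=adjustment)

    def median_by(self, factor: str) -> pd.Series:
        """Median dispersion score per level of a factor."""
        return self.scores.groupby(factor)["z"].median()

    def summary(self) -> str:
        lines = [
            f"Beta dispersion of {len(self.scores)} sequences, "
            f"{self.scores['specimen_id'].nunique()} specimens "
            f"(intra_only={self.model.intra_only})",
            "",
            "Median z by basin:",
            self.median_by("basin").to_string(),
        ]
        return "\n".join(lines)
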