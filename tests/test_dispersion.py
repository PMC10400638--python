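"""PCoA, distance-to-centroid, sequential ANOVA and rank-sum tests."""

import numpy as np
import pandas as pd
import pytest
from scipy.spatial.distance import pdist, squareform
from skbio import DistanceMatrix

from ribovar.dispersion import (
    BetaDispersion,
    distance_to_centroid,
    pairwise_wilcoxon,
    pcoa,
    sequential_anova,
)
from ribovar.io import SampleMetadata


def _dm(d, ids=None):
    n = d.shape[0]
    return DistanceMatrix(d, ids=ids or [f"s{i}" for i in range(n)])


# -- ordination ------------------------------------------------------------------

def test_pcoa_equilateral_triangle():
    d = np.ones((3, 3)) - np.eye(3)
    o = pcoa(_dm(d), transform=None)
    # two equal positive eigenvalues 0.5, one zero
    assert o.eigenvalues[:2] == pytest.approx([0.5, 0.5], abs=1e-9)
    assert abs(o.eigenvalues[2]) < 1e-9
    coords = o.coords_pos
    side = np.linalg.norm(coords[0] - coords[1])
    assert side == pytest.approx(1.0, abs=1e-9)


def test_pcoa_two_points_sqrt_transform():
    d = np.array([[0.0, 4.0], [4.0, 0.0]])
    o = pcoa(_dm(d))  # sqrt -> delta = 2 -> single eigenvalue delta^2/2 = 2
    assert o.eigenvalues[0] == pytest.approx(2.0, abs=1e-9)
    assert o.coords_neg.shape[1] == 0


def test_pcoa_euclidean_input_has_no_negative_axes():
    rng = np.random.default_rng(0)
    pts = rng.normal(size=(10, 3))
    d = squareform(pdist(pts))
    o = pcoa(_dm(d), transform=None)
    assert o.coords_neg.shape[1] == 0
    assert o.eigenvalues.min() > -1e-8
    # eigenvalue sum equals the trace of the double-centered matrix
    a = -0.5 * d**2
    j = np.eye(10) - np.ones((10, 10)) / 10
    assert o.eigenvalues.sum() == pytest.approx(np.trace(j @ a @ j), abs=1e-8)
    # squared inter-point distances recovered from the coordinates
    rec = squareform(pdist(o.coords_pos)) ** 2
    assert np.allclose(rec, d**2, atol=1e-6)


def test_pcoa_rejects_unknown_transform():
    with pytest.raises(ValueError):
        pcoa(_dm(np.zeros((2, 2))), transform="log")


# -- distance to centroid ----------------------------------------------------------

def test_singleton_group_gets_zero():
    d = np.array([[0.0, 1.0], [1.0, 0.0]])
    o = pcoa(_dm(d), transform=None)
    z = distance_to_centroid(o, ["g1", "g2"])
    assert (z["z"] == 0).all()


def test_centroid_distance_matches_geometry():
    pts = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 2.0], [0.0, 1.0]])
    d = squareform(pdist(pts))
    o = pcoa(_dm(d), transform=None)
    z = distance_to_centroid(o, ["g"] * 4)["z"].to_numpy()
    want = np.linalg.norm(pts - pts.mean(axis=0), axis=1)
    assert z == pytest.approx(want, abs=1e-9)


def test_congruent_groups_have_identical_scores():
    pts = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 2.0]])
    shifted = pts + np.array([50.0, -3.0])
    allpts = np.vstack([pts, shifted])
    d = squareform(pdist(allpts))
    o = pcoa(_dm(d), transform=None)
    z = distance_to_centroid(o, ["a"] * 3 + ["b"] * 3)["z"].to_numpy()
    assert np.sort(z[:3]) == pytest.approx(np.sort(z[3:]), abs=1e-9)


def test_non_euclidean_distances_use_subtractive_convention():
    # a metric that is not Euclidean-embeddable: sqrt of a tree-like metric
    d = np.array(
        [
            [0, 2, 6, 6],
            [2, 0, 6, 6],
            [6, 6, 0, 2],
            [6, 6, 2, 0],
        ],
        dtype=float,
    )
    o = pcoa(_dm(d), transform="sqrt")
    z = distance_to_centroid(o, ["g"] * 4)["z"].to_numpy()
    assert (z >= 0).all()


# -- sequential ANOVA ---------------------------------------------------------------

def test_single_factor_splits_perfectly():
    sc = pd.DataFrame({"z": [1.0, 1, 1, 3, 3, 3], "f": list("aaabbb")})
    tab = sequential_anova(sc, ["f"])
    assert tab.loc[0, "R2"] == pytest.approx(1.0, abs=1e-9)
    assert tab.loc[1, "SS"] == pytest.approx(0.0, abs=1e-9)
    assert tab["df"].sum() == 5


def _balanced_oracle(z, groups):
    """Closed-form one-way SS for a balanced design."""
    z = np.asarray(z, float)
    grand = z.mean()
    ss = 0.0
    for g in set(groups):
        vals = z[[i for i, x in enumerate(groups) if x == g]]
        ss += len(vals) * (vals.mean() - grand) ** 2
    return ss


def test_sequential_anova_matches_balanced_projection_oracle():
    rng = np.random.default_rng(2)
    # balanced nested design: 2 basins x 2 populations x 3 specimens
    rows = []
    for b in range(2):
        for p in range(2):
            for s in range(3):
                rows.append(
                    {
                        "basin": f"b{b}",
                        "population": f"b{b}p{p}",
                        "specimen_id": f"b{b}p{p}s{s}",
                        "z": float(rng.normal(loc=b + 0.5 * p)),
                    }
                )
    sc = pd.DataFrame(rows)
    tab = sequential_anova(sc, ["basin", "population"])
    z = sc["z"].to_numpy()
    ss_basin = _balanced_oracle(z, sc["basin"])
    # population SS: between-population SS minus the basin SS (sequential)
    ss_pop = _balanced_oracle(z, sc["population"]) - ss_basin
    assert tab.loc[0, "SS"] == pytest.approx(ss_basin, abs=1e-9)
    assert tab.loc[1, "SS"] == pytest.approx(ss_pop, abs=1e-9)
    assert tab["R2"].sum() == pytest.approx(1.0, abs=1e-9)
    assert tab["df"].sum() == len(sc) - 1


def test_anova_invariant_to_joint_permutation():
    rng = np.random.default_rng(5)
    sc = pd.DataFrame(
        {
            "z": rng.normal(size=12),
            "f": list("aabb") * 3,
            "g": list("cd") * 6,
        }
    )
    tab1 = sequential_anova(sc, ["f", "g"])
    perm = rng.permutation(12)
    tab2 = sequential_anova(sc.iloc[perm].reset_index(drop=True), ["f", "g"])
    assert np.allclose(tab1["SS"], tab2["SS"])


def test_constant_factor_rejected():
    sc = pd.DataFrame({"z": [1.0, 2.0, 3.0], "f": ["a", "a", "a"]})
    with pytest.raises(ValueError, match="constant"):
        sequential_anova(sc, ["f"])


# -- rank-sum tests -------------------------------------------------------------------

def test_wilcoxon_extreme_separation_exact():
    sc = pd.DataFrame({"z": [1, 2, 3, 4, 5, 6.0], "f": list("aaabbb")})
    tab = pairwise_wilcoxon(sc, "f")
    assert tab.loc[0, "method"] == "exact"
    assert tab.loc[0, "p"] == pytest.approx(0.1, abs=1e-12)


def test_wilcoxon_identical_samples():
    sc = pd.DataFrame({"z": [1, 2, 3, 1, 2, 3.0], "f": list("aaabbb")})
    tab = pairwise_wilcoxon(sc, "f")
    assert tab.loc[0, "p"] == pytest.approx(1.0, abs=1e-9)


def test_holm_stepdown_arithmetic():
    rng = np.random.default_rng(0)
    sc = pd.DataFrame(
        {
            "z": np.r_[rng.normal(0, 1, 8), rng.normal(3, 1, 8), rng.normal(0.2, 1, 8)],
            "f": ["a"] * 8 + ["b"] * 8 + ["c"] * 8,
        }
    )
    tab = pairwise_wilcoxon(sc, "f", adjustment="holm")
    assert (tab["p_adj"] >= tab["p"] - 1e-15).all()
    assert (tab["p_adj"] <= 1).all()
    # Holm on two raw p-values (0.01, 0.04) -> (0.02, 0.04)
    from statsmodels.stats.multitest import multipletests

    adj = multipletests([0.01, 0.04], method="holm")[1]
    assert adj == pytest.approx([0.02, 0.04], abs=1e-12)


def test_wilcoxon_single_level_rejected():
    sc = pd.DataFrame({"z": [1.0, 2.0], "f": ["a", "a"]})
    with pytest.raises(ValueError, match="fewer than 2 levels"):
        pairwise_wilcoxon(sc, "f")


# -- model object -----------------------------------------------------------------------

def _toy_metadata(n_per, pops):
    meta = []
    i = 0
    for pop, basin, status in pops:
        for s in range(n_per):
            for c in range(2):
                meta.append(
                    SampleMetadata(
                        f"x{i}", f"{pop}sp{s}", pop, basin, status, "Ia"
                    )
                )
                i += 1
    return meta


def test_betadispersion_end_to_end():
    rng = np.random.default_rng(8)
    meta = _toy_metadata(
        3, [("Eilat", "Red Sea", "native"), ("Avola", "Mediterranean", "invasion_front")]
    )
    n = len(meta)
    pts = rng.normal(size=(n, 4))
    d = squareform(pdist(pts)) ** 2  # sqrt transform recovers Euclidean
    dm = DistanceMatrix(d, ids=[m.sequence_id for m in meta])
    res = BetaDispersion(dm, meta).fit()
    assert (res.scores["z"] >= 0).all()
    assert set(res.scores.columns) >= {"z", "specimen_id", "basin", "population"}
    tab = res.anova(["basin", "population", "specimen_id"])
    assert tab["R2"].sum() == pytest.approx(1.0, abs=1e-9)
    pw = res.pairwise("basin")
    assert len(pw) == 1


def test_intra_only_matches_full_for_isolated_groups():
    """When every specimen's points are congruent and far apart, the
    specimen-submatrix scores equal the full-ordination scores."""
    pts = np.array([[0.0, 0], [1, 0], [0, 1]])
    allpts = np.vstack([pts, pts + 1000.0])
    d = squareform(pdist(allpts)) ** 2
    meta = []
    for i in range(6):
        sp = "sp1" if i < 3 else "sp2"
        meta.append(SampleMetadata(f"x{i}", sp, "p", "b", "native", "Ia"))
    dm = DistanceMatrix(d, ids=[m.sequence_id for m in meta])
    full = BetaDispersion(dm, meta).fit().scores["z"].to_numpy()
    intra = BetaDispersion(dm, meta, intra_only=True).fit().scores["z"].to_numpy()
    assert full == pytest.approx(intra, abs=1e-6)


def test_null_rejection_rate_calibrated():
    """No basin effect: Wilcoxon on basin rejects at ~alpha over simulated nulls."""
    rng = np.random.default_rng(12345)
    rejections = 0
    n_datasets = 200
    meta = _toy_metadata(
        6, [("Eilat", "Red Sea", "native"), ("Avola", "Mediterranean", "invasion_front")]
    )
    ids = [m.sequence_id for m in meta]
    for _ in range(n_datasets):
        pts = rng.normal(size=(len(meta), 5))
        d = squareform(pdist(pts))
        dm = DistanceMatrix(d, ids=ids)
        res = BetaDispersion(dm, meta).fit()
        p = res.pairwise("basin")["p_adj"].iloc[0]
        rejections += p < 0.05
    rate = rejections / n_datasets
    assert 0.02 <= rate <= 0.08
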