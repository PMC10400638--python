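"""Patristic distances and their stratification into comparison levels.

Every unordered pair of sequences is assigned to exactly one of four
hierarchical comparison levels from the sampling design:

- ``intra_genomic`` — both clones from the same specimen (gene copies of
  one genome);
- ``population`` — different specimens from the same population;
- ``regional`` — different populations within the same oceanic basin;
- ``geographical`` — different oceanic basins.
"""

from __future__ import annotations

from typing import Sequence

import dendropy
import numpy as np
import pandas as pd
from skbio import DistanceMatrix

from ribovar.io import SampleMetadata

LEVELS = ("intra_genomic", "population", "regional", "geographical")


def patristic_matrix(tree: dendropy.Tree) -> DistanceMatrix:
    """Pairwise patristic distances (path sums of branch lengths) over leaves.

    Path sums are invariant to the position of the root, so arbitrarily
    rooted newick inputs are handled identically.
    """
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return DistanceMatrix(out, ids=ids)


def _pair_label(a: str, b: str) -> str:
    return "|".join(sorted((a, b)))


def classify_pairs(
    distances: DistanceMatrix, metadata: Sequence[SampleMetadata]
) -> pd.DataFrame:
    """Assign every unordered sequence pair to its comparison level.

    Returns a DataFrame with one row per pair: ids, distance, level, and
    genotype/basin/invasion-status pair labels (sorted, ``|``-joined) so
    per-genotype panels can filter to within-genotype pairs.

    Raises ``ValueError`` if the distance-matrix ids and the metadata
    sequence ids differ, listing the symmetric difference.
    """
    meta = {m.sequence_id: m for m in metadata}
    ids = list(distances.ids)
    only_d = sorted(set(ids) - set(meta))
    only_m = sorted(set(meta) - set(ids))
    if only_d or only_m:
        raise ValueError(
            "distance matrix and metadata disagree on sequence ids; "
            f"only in distances: {only_d}; only in metadata: {only_m}"
        )
    rows = []
    for i in range(len(ids)):
        mi = meta[ids[i]]
        for j in range(i + 1, len(ids)):
            mj = meta[ids[j]]
            if mi.specimen_id == mj.specimen_id:
                level = "intra_genomic"
            elif mi.population == mj.population:
                level = "population"
            elif mi.basin == mj.basin:
                level = "regional"
            else:
                level = "geographical"
            rows.append(
                {
                    "sequence_id_1": ids[i],
                    "sequence_id_2": ids[j],
                    "distance": distances[ids[i], ids[j]],
                    "level": level,
                    "genotype_pair": _pair_label(mi.genotype, mj.genotype),
                    "basin_pair": _pair_label(mi.basin, mj.basin),
                    "status_pair": _pair_label(
                        mi.invasion_status, mj.invasion_status
                    ),
                    "within_genotype": mi.genotype == mj.genotype,
                }
            )
    df = pd.DataFrame(rows)
    df["level"] = pd.Categorical(df["level"], categories=LEVELS, ordered=True)
    return df


def level_distribution_summary(
    stratified: pd.DataFrame, within_genotype_only: bool = True
) -> pd.DataFrame:
    """Per-(genotype, level) distance distribution summary.

    Backs a box-plot-style figure: n, mean, median and quartiles of the
    patristic distance at each comparison level, per genotype. Levels with
    zero pairs for a genotype are reported with n = 0 (not dropped).

    With ``within_genotype_only`` (default) only pairs whose two members
    share a genotype contribute, and the genotype column is that shared
    genotype.
    """
    df = stratified
    if within_genotype_only:
        df = df[df["within_genotype"]].copy()
        df["genotype"] = df["genotype_pair"].str.split("|").str[0]
    else:
        df = df.copy()
        df["genotype"] = df["genotype_pair"]
    rows = []
    for genotype in sorted(df["genotype"].unique()):
        sub = df[df["genotype"] == genotype]
        for level in LEVELS:
            vals = sub.loc[sub["level"] == level, "distance"].to_numpy(float)
            if vals.size:
                rows.append(
                    {
                        "genotype": genotype,
                        "level": level,
                        "n_pairs": int(vals.size),
                        "mean": float(np.mean(vals)),
                        "median": float(np.median(vals)),
                        "q25": float(np.percentile(vals, 25)),
                        "q75": float(np.percentile(vals, 75)),
                    }
                )
            else:
                rows.append(
                    {
                        "genotype": genotype,
                        "level": level,
                        "n_pairs": 0,
                        "mean": np.nan,
                        "median": np.nan,
                        "q25": np.nan,
                        "q75": np.nan,
                    }
                )
    return pd.DataFrame(rows)
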