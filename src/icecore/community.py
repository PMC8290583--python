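"""Amplicon community profiling and permutation statistics.

Rarefaction, major-taxa selection, shared-OTU accounting, weighted UniFrac
distances, principal coordinates analysis, ANOSIM, and Mantel tests. The
distance/ordination/permutation machinery delegates to scikit-bio; this
module owns the domain plumbing (OTU tables, thresholds, selection rules)
and the conventions: normalized weighted UniFrac (distances in [0, 1]),
mid-ranks for ANOSIM ties, the +1 permutation correction (p is never 0),
and PCoA explained variance over positive eigenvalues only.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import skbio
from skbio import DistanceMatrix
from skbio.diversity import beta_diversity
from skbio.stats import distance as skbio_distance
from skbio.stats import ordination as skbio_ordination

from .io import OtuTable, UNCLASSIFIED


@dataclass
class OrdinationResult:
    """PCoA coordinates plus percent of (positive-eigenvalue) variance."""

    coordinates: pd.DataFrame  # samples x axes
    explained_pct: np.ndarray  # per retained axis
    eigvals: np.ndarray  # all eigenvalues, negatives included
    negative_eigvals: np.ndarray


def rarefy(
    table: OtuTable, depth: int, seed: int, drop_under: bool = False
) -> OtuTable:
    """Subsample every sample to exactly ``depth`` reads without replacement.

    Samples with fewer than ``depth`` reads raise an error unless
    ``drop_under`` is set, in which case they are dropped with a warning.
    """
    if depth < 1:
        raise ValueError("depth must be >= 1")
    rng = np.random.default_rng(seed)
    totals = table.counts.sum(axis=1)
    under = totals.index[totals < depth].tolist()
    if under and not drop_under:
        raise ValueError(
            f"samples with fewer than {depth} reads: {under} "
            "(pass drop_under=True to drop them)"
        )
    if under:
        warnings.warn(f"dropping samples under depth {depth}: {under}")
    keep = [s for s in table.sample_ids if s not in set(under)]
    rows = {}
    for s in keep:
        row = table.counts.loc[s].to_numpy()
        rows[s] = rng.multivariate_hypergeometric(row, depth)
    counts = pd.DataFrame(rows, index=table.otu_ids).T
    return OtuTable(
        counts=counts,
        taxonomy=table.taxonomy,
        sample_role=table.sample_role.loc[keep],
        qpcr_copies=table.qpcr_copies.loc[keep],
    )


def genus_label(lineage: str) -> str:
    """Genus key for aggregation; unclassified genera are disambiguated by
    the finest classified parent rank (e.g. ``Comamonadaceae;unclassified``)."""
    parts = lineage.split(";")
    genus = parts[-1]
    if genus != UNCLASSIFIED:
        return genus
    for parent in reversed(parts[:-1]):
        if parent != UNCLASSIFIED:
            return f"{parent};{UNCLASSIFIED}"
    return UNCLASSIFIED


def major_taxa(
    table: OtuTable,
    level: str = "genus",
    min_pct: float = 1.0,
    renormalize: bool = False,
) -> tuple[list[str], pd.DataFrame]:
    """Taxa whose relative abundance is >= ``min_pct`` percent in at least
    one sample, plus their per-sample percentage profile.

    ``level="genus"`` collapses OTUs by genus string first; ``level="otu"``
    selects individual OTUs. With ``renormalize=True`` the selected taxa's
    percentages are rescaled to sum to 100 in each sample.
    """
    if not 0 < min_pct < 100:
        raise ValueError("min_pct must be in (0, 100)")
    if level not in ("genus", "otu"):
        raise ValueError(f"unknown level {level!r}")
    pct = table.relative_abundance() * 100.0
    if level == "genus":
        labels = table.taxonomy.map(genus_label)
        pct = pct.T.groupby(labels).sum().T
    selected = [t for t in pct.columns if (pct[t] >= min_pct).any()]
    profile = pct[selected]
    if renormalize:
        totals = profile.sum(axis=1)
        profile = profile.div(totals.replace(0, np.nan), axis=0).fillna(0.0) * 100.0
    return selected, profile


def shared_otus(
    table: OtuTable, sample_a: str, sample_b: str, min_pct: float = 1.0
) -> tuple[int, int, int]:
    """Among OTUs reaching ``min_pct`` percent in at least one of the two
    samples, count (shared, a-only, b-only) presences (presence = >=1 read)."""
    for s in (sample_a, sample_b):
        if s not in table.sample_ids:
            raise ValueError(f"unknown sample id {s!r}")
    pct = table.relative_abundance() * 100.0
    eligible = pct.columns[
        (pct.loc[sample_a] >= min_pct) | (pct.loc[sample_b] >= min_pct)
    ]
    in_a = table.counts.loc[sample_a, eligible] >= 1
    in_b = table.counts.loc[sample_b, eligible] >= 1
    return int((in_a & in_b).sum()), int((in_a & ~in_b).sum()), int((~in_a & in_b).sum())


def weighted_unifrac(table: OtuTable, tree: skbio.TreeNode) -> DistanceMatrix:
    """Normalized weighted UniFrac between all sample pairs.

    d(A, B) = sum_b l_b |p_A(b) - p_B(b)| / sum_b l_b (p_A(b) + p_B(b)),
    where p_X(b) is the fraction of sample X's reads descending from branch
    b. Distances lie in [0, 1]; the normalized variant need not satisfy the
    triangle inequality, so violations are logged, not errored.
    """
    tips = {t.name for t in tree.tips()}
    present = table.counts.columns[(table.counts > 0).any(axis=0)]
    missing = set(present) - tips
    if missing:
        raise ValueError(f"OTUs with reads missing from the tree: {sorted(missing)}")
    dm = beta_diversity(
        "weighted_unifrac",
        table.counts.to_numpy(),
        ids=table.sample_ids,
        taxa=table.otu_ids,
        tree=tree,
        normalized=True,
        validate=True,
    )
    _log_triangle_violations(dm)
    return dm

def _log_triangle_violations(dm: DistanceMatrix) -> None:
    d = dm.data
    n = d.shape[0]
    viol = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.any(d[i, j] > d[i, :] + d[:, j] + 1e-12):
                viol += 1
    if viol:
        warnings.warn(f"{viol} sample pair(s) violate the triangle inequality")


def pcoa(dm: DistanceMatrix, n_axes: int = 2) -> OrdinationResult:
    """Classical metric scaling of a distance matrix.

    Explained percentages are eigenvalue shares of the summed *positive*
    eigenvalues; negative eigenvalues are excluded from the denominator and
    reported on the result.
    """
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        res = skbio_ordination.pcoa(dm, method="eigh", warn_neg_eigval=False)
    eigvals = res.eigvals.to_numpy()
    pos = eigvals[eigvals > 1e-12]
    neg = eigvals[eigvals < 0]
    n_pos = len(pos)
    if n_axes > n_pos:
        warnings.warn(
            f"requested {n_axes} axes but only {n_pos} positive eigenvalues; truncating"
        )
        n_axes = n_pos
    coords = res.samples.iloc[:, :n_axes]
    coords.index = list(dm.ids)
    explained = 100.0 * pos[:n_axes] / pos.sum()
    return OrdinationResult(
        coordinates=coords,
        explained_pct=explained,
        eigvals=eigvals,
        negative_eigvals=neg,
    )


def anosim(
    dm: DistanceMatrix,
    groups,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """ANOSIM R statistic and permutation p-value.

    R = (mean between-group rank - mean within-group rank) / (n(n-1)/4)
    over mid-ranked off-diagonal distances; p uses the +1 correction,
    (#[R_perm >= R_obs] + 1) / (n_perm + 1).
    """
    groups = pd.Series(list(groups), index=list(dm.ids))
    sizes = groups.value_counts()
    if len(sizes) < 2:
        raise ValueError("ANOSIM needs at least two groups")
    if (sizes < 2).any():
        small = sizes.index[sizes < 2].tolist()
        raise ValueError(f"groups with fewer than two samples: {small}")
    res = skbio_distance.anosim(
        dm, groups.to_numpy(), permutations=n_perm, seed=seed
    )
    return float(res["test statistic"]), float(res["p-value"])


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    n_perm: int = 999,
    seed: int | None = None,
) -> tuple[float, float]:
    """Two-tailed Mantel test: Pearson r of the off-diagonal entries and a
    permutation p-value under row/column permutations of the second matrix."""
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices must share the same ids")
    dm2 = dm2.filter(dm1.ids)
    r, p, _ = skbio_distance.mantel(
        dm1, dm2, method="pearson", permutations=n_perm,
        alternative="two-sided", seed=seed,
    )
    return float(r), float(p)
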