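"""Viral community stages: confident-contig filtering, species-level vOTU
clustering, coverage normalization, rarefaction curves, viral-cluster
categorization, and lifestyle summaries.

vOTUs (viral operational taxonomic units, a species-level proxy) group
contigs sharing >=95% nucleotide identity across 80% of their lengths; the
longest contig seeds each cluster. The aligned fraction is taken over the
SHORTER sequence of a pair, following the convention of the clustering
script lineage these cutoffs come from. The alignment engine is an in-repo
k-mer-seeded (k=15, unique seeds) diagonal chainer with exact ungapped
rescoring: adequate for the substitution-dominated divergence near the
species threshold, and cross-checked against exact dynamic programming in
the test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import CoverageTable, SequenceSet

DEFAULT_MIN_IDENTITY = 0.95
DEFAULT_MIN_COV = 0.80
DEFAULT_MIN_LEN = 10000
#: Upstream viral-prediction confidence classes accepted as "confident".
CONFIDENT_CATEGORIES = frozenset({1, 2, 4, 5})

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def filter_confident(
    contigs: SequenceSet,
    min_len: int = DEFAULT_MIN_LEN,
    categories: Iterable[int] = CONFIDENT_CATEGORIES,
) -> SequenceSet:
    """Keep contigs with length >= ``min_len`` and a confidence category in
    the allowed set. Records lacking a category are an error."""
    cats = contigs.category or {}
    missing = [rid for rid in contigs.ids if rid not in cats]
    if missing:
        raise ValueError(f"records lacking a confidence category: {missing}")
    allowed = set(categories)
    keep = [
        rid
        for rid, seq in contigs.records
        if len(seq) >= min_len and cats[rid] in allowed
    ]
    return contigs.subset(keep)


def _unique_kmer_positions(seq: str, k: int) -> dict[str, int]:
    pos: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(seq) - k + 1):
        km = seq[i : i + k]
        if km in dup:
            continue
        if km in pos:
            del pos[km]
            dup.add(km)
        else:
            pos[km] = i
    return pos


def _best_segment(match: np.ndarray, mismatch_penalty: float = 2.0):
    """Maximum-scoring ungapped segment (match +1, mismatch -penalty)."""
    s = np.where(match, 1.0, -mismatch_penalty)
    prefix = np.concatenate([[0.0], np.cumsum(s)])
    run_min = np.minimum.accumulate(prefix[:-1])
    gains = prefix[1:] - run_min
    end = int(np.argmax(gains))
    score = float(gains[end])
    start = int(np.argmin(prefix[: end + 1]))
    return start, end + 1, score  # half-open on the match array


def _blocks_one_strand(a: np.ndarray, b: np.ndarray, diags: Iterable[int]):
    blocks = []
    for diag in diags:
        a_lo = max(0, diag)
        a_hi = min(len(a), len(b) + diag)
        if a_hi - a_lo <= 0:
            continue
        match = a[a_lo:a_hi] == b[a_lo - diag : a_hi - diag]
        start, end, score = _best_segment(match)
        if score <= 0:
            continue
        n_match = int(match[start:end].sum())
        blocks.append((score, a_lo + start, a_lo + end, n_match))
    # greedy non-overlapping selection on the a-axis, best score first
    blocks.sort(key=lambda t: (-t[0], t[1]))
    chosen: list[tuple[int, int, int]] = []
    for _, s, e, m in blocks:
        if all(e <= cs or s >= ce for cs, ce, _ in chosen):
            chosen.append((s, e, m))
    total_len = sum(e - s for s, e, _ in chosen)
    total_match = sum(m for _, _, m in chosen)
    return total_len, total_match


def pairwise_ani(a: str, b: str, k: int = 15) -> tuple[float, float]:
    """(nucleotide identity, aligned fraction of the shorter sequence).

    Shared unique k-mers seed candidate diagonals; each diagonal is rescored
    exactly (ungapped) and the best non-overlapping segments are summed.
    Both strands are searched and the better one reported. Unrelated
    sequences share essentially no unique 15-mers and come back near (0, 0).
    """
    a = a.upper()
    ka = _unique_kmer_positions(a, k)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    best = (0, 0)  # (aligned_len, matches)
    for strand_seq in (b.upper(), revcomp(b.upper())):
        kb = _unique_kmer_positions(strand_seq, k)
        diags = {ka[km] - kb[km] for km in ka.keys() & kb.keys()}
        if not diags:
            continue
        b_arr = np.frombuffer(strand_seq.encode(), dtype=np.uint8)
        total_len, total_match = _blocks_one_strand(a_arr, b_arr, diags)
        if total_match > best[1]:
            best = (total_len, total_match)
    total_len, total_match = best
    if total_len == 0:
        return 0.0, 0.0
    identity = total_match / total_len
    fraction = total_len / min(len(a), len(b))
    return identity, min(fraction, 1.0)


@dataclass
class VOtuCatalog:
    """Partition of contigs into vOTUs; each cluster keeps its longest
    member (the founding seed) as representative."""

    clusters: list[tuple[str, list[str]]]
    min_identity: float = DEFAULT_MIN_IDENTITY
    min_cov: float = DEFAULT_MIN_COV

    @property
    def representative_ids(self) -> list[str]:
        return [rep for rep, _ in self.clusters]

    @property
    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters for m in members}

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"member": m, "representative": rep}
            for rep, members in self.clusters
            for m in members
        ]
        return pd.DataFrame(rows)


def cluster_votus(
    contigs: SequenceSet,
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_cov: float = DEFAULT_MIN_COV,
    k: int = 15,
) -> VOtuCatalog:
    """Greedy longest-first clustering into vOTUs.

    Contigs are processed by decreasing length (ties: lexicographically
    smaller id first); each joins the earliest cluster whose representative
    meets both thresholds, else founds a new cluster. Representatives are
    founders, hence the longest member of their cluster.
    """
    seqs = dict(contigs.records)
    order = sorted(seqs, key=lambda rid: (-len(seqs[rid]), rid))
    clusters: list[tuple[str, list[str]]] = []
    for rid in order:
        placed = False
        for idx, (rep, members) in enumerate(clusters):
            ident, frac = pairwise_ani(seqs[rep], seqs[rid], k=k)
            if ident >= min_identity and frac >= min_cov:
                members.append(rid)
                placed = True
                break
        if not placed:
            clusters.append((rid, [rid]))
    return VOtuCatalog(clusters=clusters, min_identity=min_identity, min_cov=min_cov)


def normalize_coverage(cov: CoverageTable) -> pd.DataFrame:
    """Per-gigabase coverage: depth * 1e9 / library_bp, per sample."""
    return cov.normalized


def votu_rarefaction(
    read_assignments: Sequence,
    depths: Sequence[int],
    n_reps: int = 100,
    seed: int = 0,
    min_reads: int = 1,
) -> pd.DataFrame:
    """Mean (+/- sd) number of vOTUs detected when subsampling reads.

    ``read_assignments`` gives each read's vOTU label, or None/NaN/"unmapped"
    for reads not recruited to any vOTU. A vOTU counts as detected when at
    least ``min_reads`` subsampled reads are assigned to it. Subsampling is
    without replacement.
    """
    labels = pd.Series(list(read_assignments))
    mapped = labels.notna() & (labels != "unmapped")
    votu_counts = labels[mapped].value_counts()
    n_unmapped = int((~mapped).sum())
    counts_vec = np.concatenate([votu_counts.to_numpy(), [n_unmapped]])
    total = int(counts_vec.sum())
    n_votu = len(votu_counts)
    rng = np.random.default_rng(seed)
    rows = []
    for depth in depths:
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total reads {total}")
        detected = np.empty(n_reps)
        for rep in range(n_reps):
            draw = rng.multivariate_hypergeometric(counts_vec, depth)
            detected[rep] = int((draw[:n_votu] >= min_reads).sum())
        rows.append(
            {"depth": depth, "mean_votus": detected.mean(), "sd_votus": detected.std()}
        )
    return pd.DataFrame(rows)


VC_CLASSIFIED = "classified_vc"
VC_EXCLUSIVE = "exclusive_vc"
VC_SINGLETON = "singleton"


@dataclass
class VcCategorization:
    """Genus-level (viral cluster) categorization of vOTUs.

    ``novel_genera`` counts putative new genus-level groups: distinct
    study-exclusive VCs plus singleton/outlier vOTUs.
    """

    per_votu: dict[str, str]
    n_classified: int
    n_exclusive: int
    n_singleton: int
    novel_genera: int

    @property
    def n_votus(self) -> int:
        return len(self.per_votu)

    @property
    def classified_pct(self) -> float:
        return 100.0 * self.n_classified / self.n_votus if self.per_votu else 0.0


def categorize_vcs(
    votu_ids: Sequence[str],
    vc_assignment: Mapping[str, str | None],
    vc_has_refseq: Mapping[str, bool],
) -> VcCategorization:
    """Categorize each vOTU by its viral cluster (VC).

    classified_vc: its VC contains at least one reference genome;
    exclusive_vc: its VC exists but holds only study vOTUs;
    singleton: no VC assignment (singleton or outlier).
    """
    stray = set(vc_has_refseq) - {
        vc for vc in vc_assignment.values() if vc is not None
    }
    if stray:
        warnings.warn(f"VC ids absent from the assignments: {sorted(stray)}")
    per_votu: dict[str, str] = {}
    exclusive_vcs: set[str] = set()
    for v in votu_ids:
        vc = vc_assignment.get(v)
        if vc is None:
            per_votu[v] = VC_SINGLETON
        elif vc_has_refseq.get(vc, False):
            per_votu[v] = VC_CLASSIFIED
        else:
            per_votu[v] = VC_EXCLUSIVE
            exclusive_vcs.add(vc)
    counts = pd.Series(per_votu).value_counts()
    n_singleton = int(counts.get(VC_SINGLETON, 0))
    return VcCategorization(
        per_votu=per_votu,
        n_classified=int(counts.get(VC_CLASSIFIED, 0)),
        n_exclusive=int(counts.get(VC_EXCLUSIVE, 0)),
        n_singleton=n_singleton,
        novel_genera=len(exclusive_vcs) + n_singleton,
    )


def _floor1(x: float) -> float:
    # floor to one decimal, guarding against float representation error
    return math.floor(x * 10 + 1e-9) / 10


@dataclass
class LifestyleSummary:
    n_votus: int
    n_temperate: int
    temperate_pct: float  # rounded to one decimal
    fold_vs_reference: dict[str, float]  # floor-truncated to one decimal


def lifestyle_summary(
    flags: Mapping[str, str], references: Mapping[str, float] | None = None
) -> LifestyleSummary:
    """Temperate fraction of the vOTU set and fold-enrichment versus
    reference environments' temperate percentages.

    Folds are floor-truncated to one decimal; e.g. a 42.4% temperate
    community versus a 13% reference gives a 3.2-fold enrichment.
    """
    valid = {"temperate", "lytic"}
    bad = {v: f for v, f in flags.items() if f not in valid}
    if bad:
        raise ValueError(f"lifestyle flags must be temperate|lytic; got {bad}")
    n = len(flags)
    n_temp = sum(1 for f in flags.values() if f == "temperate")
    pct = round(100.0 * n_temp / n, 1) if n else 0.0
    folds: dict[str, float] = {}
    for name, ref_pct in (references or {}).items():
        if ref_pct <= 0:
            raise ValueError(f"reference percentage for {name!r} must be > 0")
        folds[name] = _floor1(pct / ref_pct)
    return LifestyleSummary(
        n_votus=n, n_temperate=n_temp, temperate_pct=pct, fold_vs_reference=folds
    )


def mean_recruited_pct(per_sample_pct: Mapping[str, float]) -> float:
    """Mean percent of quality-controlled reads recruited to vOTUs across
    viromes, rounded to one decimal."""
    vals = list(per_sample_pct.values())
    if not vals:
        raise ValueError("no per-sample values")
    return round(float(np.mean(vals)), 1)
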