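"""In-silico virus-host prediction by three independent methods.

1. Nucleotide similarity: alignment hits between vOTUs and host genomes are
   gated at bit score >= 50 and E <= 1e-3, surviving HSPs are merged on host
   coordinates, and a host is predicted when the merged span reaches 2,000 bp
   at an alignment-length-weighted mean identity >= 70%.
2. Sequence composition: the d2* oligonucleotide-frequency dissimilarity
   (k = 6) between a vOTU and every host genome; the lowest-dissimilarity
   host is predicted when its d2* <= 0.1 and at least 80% of the 30 nearest
   hosts share its genus (the consensus operationalizes the "possibility"
   criterion of composition-based matching).
3. CRISPR spacers: arrays of >2 identical direct repeats are mined from host
   genomes, and a spacer linking host to virus must match the vOTU sequence
   (either strand) with zero mismatches.

Union and genus-level agreement across the three methods are reported by
``combine_predictions``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import SequenceSet
from .votu import revcomp

_CODE = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass
class AlignmentHit:
    """One HSP between a vOTU and a host genome (1-based inclusive coords)."""

    votu_id: str
    host_id: str
    bit_score: float
    e_value: float
    identity_pct: float
    align_len: int
    votu_start: int = 1
    votu_end: int = 1
    host_start: int = 1
    host_end: int = 1
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise ValueError("align_len must be >= 1")
        if not 0 <= self.identity_pct <= 100:
            raise ValueError("identity_pct must be within [0, 100]")
        if self.e_value < 0:
            raise ValueError("e_value must be >= 0")
        if self.host_start > self.host_end:
            self.host_start, self.host_end = self.host_end, self.host_start
            self.strand = "-" if self.strand == "+" else "+"
        if self.votu_start > self.votu_end:
            raise ValueError(
                f"malformed vOTU coordinates {self.votu_start}..{self.votu_end}"
            )


@dataclass
class CrisprArray:
    """A direct-repeat array: >=3 identical repeats separated by spacers."""

    host_id: str
    repeat: str
    spacers: list[tuple[str, int]]  # (sequence, 0-based host start)
    n_repeats: int

    def __post_init__(self) -> None:
        if self.n_repeats < 3:
            raise ValueError("a reported array needs more than 2 direct repeats")


@dataclass
class HostPrediction:
    votu_id: str
    host_id: str
    method: str  # similarity | composition | crispr
    score: dict = field(default_factory=dict)
    host_genus: str | None = None


def read_blast_hits(path) -> list[AlignmentHit]:
    """Read 12-column tabular alignment output (query = vOTU, subject = host)."""
    cols = [
        "query", "subject", "identity_pct", "align_len", "mismatches",
        "gapopens", "qstart", "qend", "sstart", "send", "evalue", "bitscore",
    ]
    df = pd.read_csv(path, sep="\t", names=cols, comment="#")
    return [
        AlignmentHit(
            votu_id=r.query, host_id=r.subject, bit_score=float(r.bitscore),
            e_value=float(r.evalue), identity_pct=float(r.identity_pct),
            align_len=int(r.align_len), votu_start=int(r.qstart),
            votu_end=int(r.qend), host_start=int(r.sstart), host_end=int(r.send),
        )
        for r in df.itertuples()
    ]


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def similarity_hosts(
    hits: Iterable[AlignmentHit],
    min_bit: float = 50.0,
    max_e: float = 1e-3,
    min_ani_pct: float = 70.0,
    min_span_bp: int = 2000,
) -> list[HostPrediction]:
    """Nucleotide-similarity host predictions.

    Per (vOTU, host): HSPs failing the bit-score or E-value gates are
    discarded; the survivors' host-coordinate intervals are merged (overlaps
    collapsed) into a total span, and their identities averaged weighted by
    alignment length. Predict when span >= ``min_span_bp`` and the weighted
    ANI >= ``min_ani_pct``.
    """
    groups: dict[tuple[str, str], list[AlignmentHit]] = {}
    for h in hits:
        if h.bit_score >= min_bit and h.e_value <= max_e:
            groups.setdefault((h.votu_id, h.host_id), []).append(h)
    preds = []
    for (votu, host), hsps in sorted(groups.items()):
        merged = _merge_intervals([(h.host_start, h.host_end) for h in hsps])
        span = sum(e - s + 1 for s, e in merged)
        w = np.array([h.align_len for h in hsps], dtype=float)
        ani = float(np.average([h.identity_pct for h in hsps], weights=w))
        if span >= min_span_bp and ani >= min_ani_pct:
            preds.append(
                HostPrediction(
                    votu_id=votu, host_id=host, method="similarity",
                    score={"ani_pct": ani, "span_bp": span, "n_hsps": len(hsps)},
                )
            )
    return preds


class _OnfProfile:
    """k-mer counts and the i.i.d.-mononucleotide expectation for one sequence."""

    def __init__(self, seq: str, k: int, strand_symmetric: bool = False):
        if len(seq) < k:
            raise ValueError(f"sequence shorter than k={k}")
        seq = seq.upper()
        if strand_symmetric:
            seq = seq + "N" + revcomp(seq)  # N breaks spurious junction words
        codes = _CODE[np.frombuffer(seq.encode(), dtype=np.uint8)]
        valid_nt = codes >= 0
        n = len(codes)
        idx = np.zeros(n - k + 1, dtype=np.int64)
        ok = np.ones(n - k + 1, dtype=bool)
        for j in range(k):
            window = codes[j : n - k + 1 + j]
            idx = idx * 4 + np.where(window >= 0, window, 0)
            ok &= window >= 0
        self.counts = np.bincount(idx[ok], minlength=4**k).astype(float)
        self.n_words = float(ok.sum())
        p_nt = np.bincount(codes[valid_nt], minlength=4).astype(float)
        p_nt /= p_nt.sum()
        p_word = np.ones(1)
        for _ in range(k):
            p_word = np.kron(p_word, p_nt)
        self.expected = self.n_words * p_word
        self.centered = self.counts - self.expected
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(self.expected > 0, self.centered**2 / self.expected, 0.0)
        self.norm = float(np.sqrt(contrib.sum()))


def _d2star_from_profiles(px: _OnfProfile, py: _OnfProfile) -> float:
    mask = (px.expected > 0) & (py.expected > 0)
    denom = np.sqrt(px.expected[mask] * py.expected[mask])
    d2 = float(np.sum(px.centered[mask] * py.centered[mask] / denom))
    if px.norm == 0 or py.norm == 0:
        return 0.5
    val = 0.5 * (1.0 - d2 / (px.norm * py.norm))
    return float(min(max(val, 0.0), 1.0))


def onf_dissimilarity(
    a: str, b: str, k: int = 6, strand_symmetric: bool = False
) -> float:
    """d2* oligonucleotide-frequency dissimilarity in [0, 1].

    Word counts are centered by their expectation under an i.i.d.
    mononucleotide null fitted per sequence, the cross term is scaled by the
    geometric mean of the two expectations, and each norm uses its own
    variance scaling. Identical sequences score 0; the conventional
    host-assignment threshold is 0.1. Words are counted on the forward
    strand by default. Sequences shorter than ~5 kb give noisy estimates
    (warned); shorter than k is an error.
    """
    for name, s in (("a", a), ("b", b)):
        if len(s) < k:
            raise ValueError(f"sequence {name} shorter than k={k}")
        if len(s) < 5000:
            warnings.warn(f"sequence {name} shorter than 5 kb; d2* will be noisy")
    return _d2star_from_profiles(
        _OnfProfile(a, k, strand_symmetric), _OnfProfile(b, k, strand_symmetric)
    )


def composition_hosts(
    votus: SequenceSet,
    hosts: SequenceSet,
    host_genus: Mapping[str, str],
    max_d: float = 0.1,
    min_consensus_pct: float = 80.0,
    top_n: int = 30,
    k: int = 6,
    strand_symmetric: bool = False,
) -> list[HostPrediction]:
    """Composition-based host predictions.

    Per vOTU, hosts are ranked by d2* ascending; the rank-1 host is
    predicted when its dissimilarity is <= ``max_d`` and at least
    ``min_consensus_pct`` percent of the ``top_n`` nearest hosts share its
    genus (all hosts when fewer than ``top_n`` are available).
    """
    if len(hosts) == 0:
        raise ValueError("empty host set")
    missing = set(hosts.ids) - set(host_genus)
    if missing:
        raise ValueError(f"hosts missing a genus: {sorted(missing)}")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        host_profiles = {
            hid: _OnfProfile(seq, k, strand_symmetric) for hid, seq in hosts.records
        }
        preds = []
        for vid, vseq in votus.records:
            pv = _OnfProfile(vseq, k, strand_symmetric)
            d = pd.Series(
                {hid: _d2star_from_profiles(pv, hp) for hid, hp in host_profiles.items()}
            ).sort_values(kind="stable")
            top = d.iloc[: min(top_n, len(d))]
            candidate = top.index[0]
            genus = host_genus[candidate]
            consensus = 100.0 * np.mean([host_genus[h] == genus for h in top.index])
            if top.iloc[0] <= max_d and consensus >= min_consensus_pct:
                preds.append(
                    HostPrediction(
                        votu_id=vid, host_id=candidate, method="composition",
                        host_genus=genus,
                        score={
                            "dissimilarity": float(top.iloc[0]),
                            "consensus_pct": float(consensus),
                        },
                    )
                )
    return preds


def find_crispr_arrays(
    genome: str,
    host_id: str = "",
    min_repeats: int = 3,
    repeat_len: tuple[int, int] = (23, 47),
    spacer_len: tuple[int, int] = (26, 50),
) -> list[CrisprArray]:
    """Mine exact direct-repeat arrays from a host genome.

    Scans for >= ``min_repeats`` identical copies of a repeat (length within
    ``repeat_len``) separated by distinct spacers (length within
    ``spacer_len``); maximal non-overlapping arrays are reported. Exact
    repeats only: fuzzy repeat matching is deliberately out of scope.
    """
    genome = genome.upper()
    k = repeat_len[0]
    if len(genome) < min_repeats * k:
        return []
    positions: dict[str, list[int]] = {}
    for i in range(len(genome) - k + 1):
        positions.setdefault(genome[i : i + k], []).append(i)

    lo_gap = repeat_len[0] + spacer_len[0]
    hi_gap = repeat_len[1] + spacer_len[1]
    arrays: list[CrisprArray] = []
    covered: list[tuple[int, int]] = []
    for km in sorted(positions, key=lambda km: positions[km][0]):
        occ = positions[km]
        if len(occ) < min_repeats:
            continue
        # chain occurrences whose start-to-start gaps fit a repeat+spacer unit
        i = 0
        while i < len(occ):
            chain = [occ[i]]
            j = i
            while j + 1 < len(occ) and lo_gap <= occ[j + 1] - occ[j] <= hi_gap:
                chain.append(occ[j + 1])
                j += 1
            i = j + 1
            if len(chain) < min_repeats:
                continue
            if any(chain[0] < ce and chain[-1] + k > cs for cs, ce in covered):
                continue  # inner seed of an already-reported array
            array = _extend_array(genome, chain, k, repeat_len, spacer_len)
            if array is None:
                continue
            repeat, spacers = array
            if len({s for s, _ in spacers}) != len(spacers):
                continue  # repeats must be separated by unique spacers
            arrays.append(
                CrisprArray(
                    host_id=host_id, repeat=repeat, spacers=spacers,
                    n_repeats=len(chain),
                )
            )
            covered.append((chain[0], chain[-1] + len(repeat)))
    return arrays


def _extend_array(genome, chain, k, repeat_len, spacer_len):
    """Extend the seed k-mer rightwards while every copy agrees and the
    resulting spacers stay within the allowed length range."""
    gaps = [b - a for a, b in zip(chain, chain[1:])]
    max_ext = min(
        repeat_len[1] - k,
        min(gaps) - k - spacer_len[0],
        len(genome) - (chain[-1] + k),
    )
    ext = 0
    while ext < max_ext:
        nxt = {genome[p + k + ext] for p in chain}
        if len(nxt) != 1:
            break
        ext += 1
    rlen = k + ext
    spacers = []
    for a, b in zip(chain, chain[1:]):
        start = a + rlen
        spacer = genome[start:b]
        if not spacer_len[0] <= len(spacer) <= spacer_len[1]:
            return None
        spacers.append((spacer, start))
    return genome[chain[0] : chain[0] + rlen], spacers


def _count_mismatches(a: np.ndarray, b: np.ndarray) -> int:
    return int((a != b).sum())


def match_spacers(
    arrays: Iterable[CrisprArray],
    votus: SequenceSet,
    max_mismatch: int = 0,
) -> list[HostPrediction]:
    """CRISPR spacer matching: a spacer links its host to a vOTU when it
    occurs within ``max_mismatch`` substitutions (default: exact) on either
    strand of the vOTU sequence."""
    matched: dict[tuple[str, str], int] = {}
    for arr in arrays:
        for spacer, _ in arr.spacers:
            rc = revcomp(spacer)
            for vid, vseq in votus.records:
                if max_mismatch == 0:
                    hit = spacer in vseq or rc in vseq
                else:
                    hit = _fuzzy_contains(vseq, spacer, max_mismatch) or _fuzzy_contains(
                        vseq, rc, max_mismatch
                    )
                if hit:
                    key = (vid, arr.host_id)
                    matched[key] = matched.get(key, 0) + 1
    return [
        HostPrediction(
            votu_id=v, host_id=h, method="crispr", score={"matched_spacers": n}
        )
        for (v, h), n in sorted(matched.items())
    ]


def _fuzzy_contains(seq: str, pattern: str, max_mismatch: int) -> bool:
    s = np.frombuffer(seq.encode(), dtype=np.uint8)
    p = np.frombuffer(pattern.encode(), dtype=np.uint8)
    m = len(p)
    for off in range(len(s) - m + 1):
        if _count_mismatches(s[off : off + m], p) <= max_mismatch:
            return True
    return False


def combine_predictions(
    similarity: Sequence[HostPrediction],
    composition: Sequence[HostPrediction],
    crispr: Sequence[HostPrediction],
    host_genus: Mapping[str, str] | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Union the three methods' predictions and count genus-level agreement.

    Returns a tidy table (one row per prediction, with method provenance)
    and a report dict with the union of linked vOTUs, per-method counts, and
    the number of (vOTU, method-pair) combinations predicting the same host
    genus.
    """
    all_preds = list(similarity) + list(composition) + list(crispr)
    genus_of: dict[str, str] = dict(host_genus or {})
    for p in all_preds:
        if p.host_genus is not None:
            if p.host_id in genus_of and genus_of[p.host_id] != p.host_genus:
                raise ValueError(
                    f"conflicting genus for host {p.host_id!r}: "
                    f"{genus_of[p.host_id]!r} vs {p.host_genus!r}"
                )
            genus_of.setdefault(p.host_id, p.host_genus)

    rows = [
        {
            "votu_id": p.votu_id,
            "host_id": p.host_id,
            "host_genus": genus_of.get(p.host_id),
            "method": p.method,
            **p.score,
        }
        for p in all_preds
    ]
    table = pd.DataFrame(
        rows, columns=["votu_id", "host_id", "host_genus", "method"]
        if not rows else None,
    )
    if rows:
        table = table.sort_values(["votu_id", "method", "host_id"]).reset_index(drop=True)

    by_method: dict[str, dict[str, set[str]]] = {}
    for p in all_preds:
        g = p.host_genus or genus_of.get(p.host_id)
        if g is not None:
            by_method.setdefault(p.method, {}).setdefault(p.votu_id, set()).add(g)
    methods = ["similarity", "composition", "crispr"]
    agreement = 0
    union_votus = sorted({p.votu_id for p in all_preds})
    for v in union_votus:
        for i, m1 in enumerate(methods):
            for m2 in methods[i + 1 :]:
                g1 = by_method.get(m1, {}).get(v, set())
                g2 = by_method.get(m2, {}).get(v, set())
                if g1 & g2:
                    agreement += 1
    report = {
        "n_votus_linked": len(union_votus),
        "votus_linked": union_votus,
        "n_by_method": {
            m: len({p.votu_id for p in all_preds if p.method == m}) for m in methods
        },
        "genus_agreement_pairs": agreement,
    }
    return table, report
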