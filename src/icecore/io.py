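"""Readers, writers, and domain containers for the pipeline's external formats.

All tabular formats are plain TSV so outputs stay diffable. On disk, OTU
tables are samples-as-columns (one row per OTU, RDP-style); in memory the
count matrix is samples-as-rows, which is the natural orientation for the
per-sample operations downstream (rarefaction, relative abundance,
distances). Counts must be integers at ingest; relative abundances are
always derived, never stored.
"""

from __future__ import annotations

import io as _io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import skbio
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

ICE_SAMPLE = "ice_sample"
BACKGROUND_CONTROL = "background_control"
ROLES = (ICE_SAMPLE, BACKGROUND_CONTROL)

#: Fixed lineage depth (domain;phylum;class;order;family;genus), padded with
#: "unclassified" at unresolved ranks.
TAXONOMY_RANKS = 6
UNCLASSIFIED = "unclassified"

VALID_BASES = frozenset("ACGTN")


def pad_lineage(lineage: str) -> str:
    """Normalize a ';'-separated lineage to exactly six ranks."""
    parts = [p.strip() or UNCLASSIFIED for p in lineage.split(";")]
    parts = parts[:TAXONOMY_RANKS]
    parts += [UNCLASSIFIED] * (TAXONOMY_RANKS - len(parts))
    return ";".join(parts)


@dataclass
class OtuTable:
    """Samples x OTUs integer count matrix with taxonomy, roles, and qPCR loads.

    Attributes
    ----------
    counts : pd.DataFrame
        Rows are samples, columns are OTUs; non-negative integer read counts.
    taxonomy : pd.Series
        Per-OTU lineage string (six ';'-separated ranks).
    sample_role : pd.Series
        Per-sample role, ``"ice_sample"`` or ``"background_control"``.
    qpcr_copies : pd.Series
        Per-sample 16S rRNA gene copies per extraction (non-negative reals).
    """

    counts: pd.DataFrame
    taxonomy: pd.Series
    sample_role: pd.Series
    qpcr_copies: pd.Series

    def __post_init__(self) -> None:
        self.counts = self.counts.copy()
        if self.counts.columns.duplicated().any():
            dups = self.counts.columns[self.counts.columns.duplicated()].tolist()
            raise ValueError(f"duplicate OTU ids: {dups}")
        if self.counts.index.duplicated().any():
            dups = self.counts.index[self.counts.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        arr = self.counts.to_numpy()
        if not np.issubdtype(arr.dtype, np.number):
            raise ValueError("counts must be numeric")
        if np.any(arr < 0):
            s, o = np.argwhere(arr < 0)[0]
            raise ValueError(
                f"negative count at sample {self.counts.index[s]!r}, "
                f"OTU {self.counts.columns[o]!r}"
            )
        if not np.allclose(arr, np.round(arr)):
            s, o = np.argwhere(arr != np.round(arr))[0]
            raise ValueError(
                f"non-integer count at sample {self.counts.index[s]!r}, "
                f"OTU {self.counts.columns[o]!r}"
            )
        self.counts = self.counts.astype(np.int64)

        missing = set(self.counts.columns) - set(self.taxonomy.index)
        if missing:
            raise ValueError(f"OTUs missing taxonomy: {sorted(missing)}")
        self.taxonomy = self.taxonomy.reindex(self.counts.columns).map(pad_lineage)

        for name, sidecar in (("role", self.sample_role), ("qPCR", self.qpcr_copies)):
            unknown = set(sidecar.index) - set(self.counts.index)
            if unknown:
                raise ValueError(f"unknown samples in {name} sidecar: {sorted(unknown)}")
            absent = set(self.counts.index) - set(sidecar.index)
            if absent:
                raise ValueError(f"samples missing a {name} value: {sorted(absent)}")
        self.sample_role = self.sample_role.reindex(self.counts.index)
        bad = ~self.sample_role.isin(ROLES)
        if bad.any():
            raise ValueError(
                f"invalid roles for samples {self.sample_role.index[bad].tolist()}; "
                f"expected one of {ROLES}"
            )
        self.qpcr_copies = self.qpcr_copies.reindex(self.counts.index).astype(float)
        if (self.qpcr_copies < 0).any():
            raise ValueError("qpcr_copies must be >= 0")

    @property
    def otu_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def ice_samples(self) -> list[str]:
        return list(self.sample_role.index[self.sample_role == ICE_SAMPLE])

    @property
    def controls(self) -> list[str]:
        return list(self.sample_role.index[self.sample_role == BACKGROUND_CONTROL])

    def relative_abundance(self) -> pd.DataFrame:
        """Per-sample proportions; all-zero samples yield all-zero rows."""
        totals = self.counts.sum(axis=1).astype(float)
        safe = totals.replace(0, np.nan)
        return self.counts.div(safe, axis=0).fillna(0.0)

    def subset_otus(self, otu_ids: Sequence[str]) -> "OtuTable":
        return OtuTable(
            counts=self.counts[list(otu_ids)],
            taxonomy=self.taxonomy.loc[list(otu_ids)],
            sample_role=self.sample_role,
            qpcr_copies=self.qpcr_copies,
        )


def _sorted_frame(df: pd.DataFrame) -> pd.DataFrame:
    # deterministic (sorted) axes so written tables are diffable
    return df.sort_index(axis=0).sort_index(axis=1)


def read_otu_table(path, roles_path, qpcr_path) -> OtuTable:
    """Read an OTU table (rows=OTUs, cols=samples, final ``taxonomy`` column)
    plus its role and qPCR sidecars.
    """
    raw = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if raw.index.duplicated().any():
        raise ValueError(
            f"duplicate OTU ids in {path}: "
            f"{raw.index[raw.index.duplicated()].unique().tolist()}"
        )
    if "taxonomy" in raw.columns:
        taxonomy = raw["taxonomy"].astype(str)
        raw = raw.drop(columns=["taxonomy"])
    else:
        taxonomy = pd.Series(UNCLASSIFIED, index=raw.index)
    counts = raw.apply(pd.to_numeric).T  # in-memory: samples as rows

    roles = pd.read_csv(roles_path, sep="\t", index_col=0).iloc[:, 0]
    qpcr = pd.read_csv(qpcr_path, sep="\t", index_col=0).iloc[:, 0]
    return OtuTable(counts=counts, taxonomy=taxonomy, sample_role=roles, qpcr_copies=qpcr)


def write_otu_table(table: OtuTable, path, roles_path=None, qpcr_path=None) -> None:
    out = _sorted_frame(table.counts).T  # on disk: samples as columns
    out["taxonomy"] = table.taxonomy.reindex(out.index)
    out.to_csv(path, sep="\t", index_label="otu_id")
    if roles_path is not None:
        table.sample_role.sort_index().to_csv(
            roles_path, sep="\t", index_label="sample_id", header=["role"]
        )
    if qpcr_path is not None:
        table.qpcr_copies.sort_index().to_csv(
            qpcr_path, sep="\t", index_label="sample_id", header=["qpcr_copies"]
        )


@dataclass
class SequenceSet:
    """Uppercase DNA records (viral contigs or host genomes).

    ``category`` optionally carries the upstream viral-prediction confidence
    class (1-5) per record; ``source_sample`` tags provenance.
    """

    records: list[tuple[str, str]]
    category: dict[str, int] | None = None
    source_sample: dict[str, str] | None = None

    def __post_init__(self) -> None:
        seen: set[str] = set()
        norm = []
        for rid, seq in self.records:
            if rid in seen:
                raise ValueError(f"duplicate sequence id: {rid!r}")
            seen.add(rid)
            if not seq:
                raise ValueError(f"empty sequence for record {rid!r}")
            seq = seq.upper()
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"record {rid!r} contains non-IUPAC characters {sorted(bad)}"
                )
            norm.append((rid, seq))
        self.records = norm
        if self.category is not None:
            bad_cat = {r: c for r, c in self.category.items() if c not in {1, 2, 3, 4, 5}}
            if bad_cat:
                raise ValueError(f"invalid confidence categories: {bad_cat}")

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.records]

    @property
    def lengths(self) -> dict[str, int]:
        return {rid: len(seq) for rid, seq in self.records}

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, rid: str) -> str:
        for r, s in self.records:
            if r == rid:
                return s
        raise KeyError(rid)

    def subset(self, ids: Sequence[str]) -> "SequenceSet":
        keep = set(ids)
        return SequenceSet(
            records=[(r, s) for r, s in self.records if r in keep],
            category={r: c for r, c in (self.category or {}).items() if r in keep}
            if self.category is not None
            else None,
            source_sample={r: s for r, s in (self.source_sample or {}).items() if r in keep}
            if self.source_sample is not None
            else None,
        )


def read_fasta(path) -> SequenceSet:
    """Read FASTA; ids are the first whitespace-delimited token, sequences
    uppercased and restricted to {A,C,G,T,N}."""
    records = []
    for rec in SeqIO.parse(str(path), "fasta"):
        records.append((rec.id, str(rec.seq)))
    return SequenceSet(records=records)


def write_fasta(seqs: SequenceSet, path, width: int = 80) -> None:
    recs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in seqs.records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(recs)


@dataclass
class CoverageTable:
    """vOTU x sample mean per-base coverage with per-sample library sizes.

    ``normalized`` is coverage per gigabase of virome:
    ``depth * 1e9 / library_bp``, elementwise by sample.
    """

    depth: pd.DataFrame  # rows = vOTUs, columns = samples
    library_bp: pd.Series  # per-sample sequenced bases

    def __post_init__(self) -> None:
        if (self.depth.to_numpy() < 0).any():
            raise ValueError("coverage depths must be >= 0")
        missing = set(self.depth.columns) - set(self.library_bp.index)
        if missing:
            raise ValueError(f"samples missing library_bp: {sorted(missing)}")
        self.library_bp = self.library_bp.reindex(self.depth.columns).astype(float)

    @property
    def votu_ids(self) -> list[str]:
        return list(self.depth.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.depth.columns)

    @property
    def normalized(self) -> pd.DataFrame:
        if (self.library_bp <= 0).any():
            bad = self.library_bp.index[self.library_bp <= 0].tolist()
            raise ValueError(f"library_bp must be > 0 to normalize; offending: {bad}")
        return self.depth * 1e9 / self.library_bp


def read_coverage_table(path) -> CoverageTable:
    """Read a coverage TSV whose first row (id ``library_bp``) holds the
    per-sample sequenced bases; remaining rows are vOTU mean depths."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if "library_bp" not in df.index:
        raise ValueError(f"{path} lacks the required 'library_bp' row")
    library_bp = df.loc["library_bp"].astype(float)
    depth = df.drop(index="library_bp").astype(float)
    return CoverageTable(depth=depth, library_bp=library_bp)


def write_coverage_table(cov: CoverageTable, path) -> None:
    out = _sorted_frame(cov.depth)
    head = cov.library_bp.reindex(out.columns).to_frame().T
    head.index = ["library_bp"]
    pd.concat([head, out]).to_csv(path, sep="\t", index_label="votu_id")


def read_newick(path) -> skbio.TreeNode:
    """Read a rooted newick tree; duplicate leaf names are an error, and
    absent branch lengths default to 0 with a warning."""
    # underscores are significant in OTU ids; disable newick's space convention
    tree = skbio.TreeNode.read(str(path), format="newick", convert_underscores=False)
    names = [t.name for t in tree.tips()]
    dup = {n for n in names if names.count(n) > 1}
    if dup:
        raise ValueError(f"duplicate leaf names in tree: {sorted(dup)}")
    n_missing = 0
    for node in tree.traverse(include_self=False):
        if node.length is None:
            node.length = 0.0
            n_missing += 1
        elif node.length < 0:
            raise ValueError(f"negative branch length on node {node.name!r}")
    if tree.length is None:
        tree.length = 0.0
    if n_missing:
        warnings.warn(
            f"{n_missing} branch(es) had no length; defaulted to 0", stacklevel=2
        )
    return tree


def write_newick(tree: skbio.TreeNode, path) -> None:
    tree.write(str(path), format="newick")


def load_config(path) -> dict:
    """Load a YAML pipeline/simulation configuration into a plain dict."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"config {path} must be a mapping")
    return cfg
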