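"""Synthetic amplicon studies and virome fixtures with known ground truth.

The amplicon generator emulates the contamination structure of a
low-biomass ice-core study: genuine ice taxa with log-normal abundance
profiles, a set of contaminant OTUs that dominate the background controls,
per-sample qPCR loads two orders of magnitude lower in controls than in ice
(blanks carry little template), and a small carryover of the contaminant
profile into the ice libraries. Under this construction the R-OTU statistic
separates planted contaminants from genuine taxa by a wide margin:
contaminants sit near R = (control:ice load ratio)/carryover (about 1 at
defaults) while genuine taxa sit near R = cross_talk * load ratio
(about 2e-4), versus the 0.01 decision threshold.

The virome generator plants near-duplicate contigs at a specified identity
over a specified shared fraction of length (substitutions only, so identity
is exact by construction), host genomes carrying a homologous region of
their linked virus, and CRISPR arrays whose spacers are copied verbatim from
the linked virus.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import (
    BACKGROUND_CONTROL,
    ICE_SAMPLE,
    CoverageTable,
    OtuTable,
    SequenceSet,
    pad_lineage,
)

#: Control names mirror a four-control design: cold-room air, a sterile
#: artificial ice core, an extraction blank, and a sequencing blank.
DEFAULT_CONTROL_NAMES = ("AirColdRoom", "ArtificialIce", "Blank", "BlankSequencing")

_ICE_GENERA = [
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Oxalobacteraceae;Janthinobacterium",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;Polaromonas",
    "Bacteria;Bacteroidetes;Flavobacteriia;Flavobacteriales;Flavobacteriaceae;Flavobacterium",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Methylobacteriaceae;Methylobacterium",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Oxalobacteraceae;Herminiimonas",
    "Bacteria;Actinobacteria;Actinobacteria;Actinomycetales;Microbacteriaceae;unclassified",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Comamonadaceae;unclassified",
    "Bacteria;Bacteroidetes;Cytophagia;Cytophagales;Cytophagaceae;Hymenobacter",
    "Bacteria;Actinobacteria;Actinobacteria;Actinomycetales;Nocardioidaceae;Nocardioides",
]
_CONTAM_GENERA = [
    "Bacteria;Actinobacteria;Actinobacteria;Propionibacteriales;Propionibacteriaceae;Cutibacterium",
    "Bacteria;Proteobacteria;Betaproteobacteria;Burkholderiales;Burkholderiaceae;Ralstonia",
    "Bacteria;Proteobacteria;Alphaproteobacteria;Rhizobiales;Bradyrhizobiaceae;Bradyrhizobium",
    "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
    "Bacteria;Proteobacteria;Gammaproteobacteria;Pseudomonadales;Moraxellaceae;Acinetobacter",
]

_BASES = np.array(list("ACGT"))


@dataclass
class AmpliconSimParams:
    """Study conditions for the synthetic amplicon experiment.

    Defaults mirror the emulated design: eight ice samples from two cores,
    four background controls, libraries of 24,000 reads, control qPCR loads
    about 100-fold below ice loads, and 1% contaminant carryover into ice.
    """

    n_true_otus: int = 120
    n_contam_otus: int = 30
    n_ice_samples: int = 8
    n_controls: int = 4
    lognormal_mu: float = 0.0
    lognormal_sigma: float = 2.0
    sample_depth: int = 24000
    qpcr_ice_range: tuple[float, float] = (1e6, 1e7)
    qpcr_control_range: tuple[float, float] = (1e4, 1e5)
    contam_carryover: float = 0.01
    #: Fraction of each control library drawn from the mean ice profile
    #: (models sample-to-blank cross-talk; keeps specificity non-trivial).
    cross_talk: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        for name in ("n_true_otus", "n_contam_otus", "n_ice_samples", "n_controls"):
            if getattr(self, name) < (0 if name == "n_contam_otus" else 1):
                raise ValueError(f"{name} too small")
        if self.sample_depth < 1:
            raise ValueError("sample_depth must be >= 1")
        for rng_name in ("qpcr_ice_range", "qpcr_control_range"):
            lo, hi = getattr(self, rng_name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{rng_name} must be positive and ordered")
        if not 0 <= self.contam_carryover <= 1:
            raise ValueError("contam_carryover must be in [0, 1]")
        if self.n_contam_otus > 0 and self.n_controls < 1:
            raise ValueError("contamination requested but no controls")


@dataclass
class ViromeSimParams:
    """Study conditions for the synthetic virome."""

    n_viral_genomes: int = 10
    genome_len_range: tuple[int, int] = (10000, 25000)
    #: (identity fraction, shared-length fraction) per planted near-duplicate.
    duplicate_pairs: list[tuple[float, float]] = field(
        default_factory=lambda: [(0.96, 0.90)]
    )
    n_host_genomes: int = 6
    host_len: int = 30000
    planted_homology_len: int = 2500
    planted_homology_identity: float = 0.85
    planted_spacers_per_host: int = 3
    repeat_len: int = 30
    spacer_len_range: tuple[int, int] = (30, 40)
    coverage_lognormal: tuple[float, float] = (1.0, 1.0)
    library_bp: float = 2e9
    n_samples: int = 2
    seed: int = 0

    def validate(self) -> None:
        if self.n_viral_genomes < 1 or self.n_host_genomes < 0:
            raise ValueError("genome counts too small")
        for ident, frac in self.duplicate_pairs:
            if not 0 < ident <= 1:
                raise ValueError(f"duplicate identity {ident} outside (0, 1]")
            if not 0 < frac <= 1:
                raise ValueError(f"shared fraction {frac} outside (0, 1]")
        if self.planted_homology_len < 0:
            raise ValueError("planted_homology_len must be >= 0")
        if not 23 <= self.repeat_len <= 47:
            raise ValueError("repeat_len outside the 23-47 bp CRISPR range")
        if self.spacer_len_range[1] >= self.genome_len_range[0]:
            raise ValueError("spacer length exceeds the shortest viral genome")


@dataclass
class GroundTruth:
    """Planted truth labels used to score downstream stages."""

    contaminant_otu_ids: list[str] = field(default_factory=list)
    duplicate_cluster_map: dict[str, str] = field(default_factory=dict)
    host_links: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"kind": "contaminant_otu", "id": o} for o in self.contaminant_otu_ids]
        rows += [
            {"kind": "duplicate_cluster", "id": g, "value": c}
            for g, c in self.duplicate_cluster_map.items()
        ]
        rows += [
            {"kind": "host_link", "id": h["votu_id"], "value": h["host_id"],
             "mechanism": h["mechanism"]}
            for h in self.host_links
        ]
        return pd.DataFrame(rows)

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return 10 ** rng.uniform(np.log10(lo), np.log10(hi), size=n)


def simulate_amplicon_study(params: AmpliconSimParams) -> tuple[OtuTable, GroundTruth]:
    """Generate a contamination-structured amplicon study with truth labels."""
    params.validate()
    rng = np.random.default_rng(params.seed)

    true_ids = [f"OTU_true_{i:04d}" for i in range(params.n_true_otus)]
    contam_ids = [f"OTU_contam_{i:04d}" for i in range(params.n_contam_otus)]
    otu_ids = true_ids + contam_ids

    ice_names = [f"Ice{i + 1}" for i in range(params.n_ice_samples)]
    ctrl_names = list(DEFAULT_CONTROL_NAMES[: params.n_controls])
    ctrl_names += [
        f"Control{i + 1}" for i in range(len(ctrl_names), params.n_controls)
    ]

    # per-ice-sample log-normal profiles over the genuine taxa
    true_prof = rng.lognormal(
        params.lognormal_mu, params.lognormal_sigma,
        size=(params.n_ice_samples, params.n_true_otus),
    )
    true_prof /= true_prof.sum(axis=1, keepdims=True)

    # one contaminant profile per control (shared contaminant pool)
    if params.n_contam_otus:
        contam_prof = rng.lognormal(
            params.lognormal_mu, params.lognormal_sigma,
            size=(params.n_controls, params.n_contam_otus),
        )
        contam_prof /= contam_prof.sum(axis=1, keepdims=True)
        mean_contam = contam_prof.mean(axis=0)
    else:
        contam_prof = np.zeros((params.n_controls, 0))
        mean_contam = np.zeros(0)
    mean_true = true_prof.mean(axis=0)

    comps = {}
    for i, s in enumerate(ice_names):
        contam_part = params.contam_carryover * mean_contam
        comp = np.concatenate([true_prof[i] * (1 - contam_part.sum()), contam_part])
        comps[s] = comp / comp.sum()
    for j, s in enumerate(ctrl_names):
        comp = np.concatenate(
            [params.cross_talk * mean_true, (1 - params.cross_talk) * contam_prof[j]]
        )
        if comp.sum() == 0:  # no contaminants simulated: controls get cross-talk only
            comp = np.concatenate([mean_true, np.zeros(0)])
        comps[s] = comp / comp.sum()

    counts = pd.DataFrame(
        {
            s: rng.multinomial(params.sample_depth, comps[s])
            for s in ice_names + ctrl_names
        },
        index=otu_ids,
    ).T

    # the control range describes a blank whose template is dominated by
    # contaminants; with no contaminants simulated, only the cross-talk
    # carryover remains and the blank's copy load shrinks accordingly
    ctrl_load_scale = 1.0 if params.n_contam_otus > 0 else max(params.cross_talk, 1e-6)
    qpcr = pd.Series(
        np.concatenate(
            [
                _log_uniform(rng, *params.qpcr_ice_range, params.n_ice_samples),
                ctrl_load_scale
                * _log_uniform(rng, *params.qpcr_control_range, params.n_controls),
            ]
        ),
        index=ice_names + ctrl_names,
    )
    roles = pd.Series(
        [ICE_SAMPLE] * params.n_ice_samples + [BACKGROUND_CONTROL] * params.n_controls,
        index=ice_names + ctrl_names,
    )
    taxonomy = pd.Series(
        [pad_lineage(_ICE_GENERA[i % len(_ICE_GENERA)]) for i in range(len(true_ids))]
        + [
            pad_lineage(_CONTAM_GENERA[i % len(_CONTAM_GENERA)])
            for i in range(len(contam_ids))
        ],
        index=otu_ids,
    )

    table = OtuTable(
        counts=counts, taxonomy=taxonomy, sample_role=roles, qpcr_copies=qpcr
    )
    return table, GroundTruth(contaminant_otu_ids=contam_ids)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(_BASES[rng.integers(0, 4, size=length)])


def _mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitute exactly round((1-identity)*len) positions to different bases."""
    n_mut = int(round((1 - identity) * len(seq)))
    if n_mut == 0:
        return seq
    pos = rng.choice(len(seq), size=n_mut, replace=False)
    arr = np.array(list(seq))
    for p in pos:
        choices = [b for b in "ACGT" if b != arr[p]]
        arr[p] = choices[rng.integers(0, 3)]
    return "".join(arr)


def simulate_virome(
    params: ViromeSimParams,
) -> tuple[SequenceSet, SequenceSet, CoverageTable, GroundTruth]:
    """Generate viral contigs with planted near-duplicates, host genomes with
    planted homology / CRISPR arrays, and a coverage table."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    truth = GroundTruth()

    viral: list[tuple[str, str]] = []
    category: dict[str, int] = {}
    base_ids = []
    for i in range(params.n_viral_genomes):
        vid = f"vOTU_{i:03d}"
        length = int(rng.integers(*params.genome_len_range, endpoint=True))
        viral.append((vid, _random_seq(rng, length)))
        category[vid] = int(rng.choice([1, 2, 4, 5]))
        base_ids.append(vid)
        truth.duplicate_cluster_map[vid] = vid

    for d, (ident, frac) in enumerate(params.duplicate_pairs):
        src_id = base_ids[d % len(base_ids)]
        src = dict(viral)[src_id]
        shared = int(round(frac * len(src)))
        dup = _mutate(rng, src[:shared], ident) + _random_seq(rng, len(src) - shared)
        did = f"{src_id}_dup{d}"
        viral.append((did, dup))
        category[did] = category[src_id]
        truth.duplicate_cluster_map[did] = src_id

    viral_set = SequenceSet(records=viral, category=category)

    hosts: list[tuple[str, str]] = []
    for h in range(params.n_host_genomes):
        hid = f"host_{h:03d}"
        genome = _random_seq(rng, params.host_len)
        linked = base_ids[h % len(base_ids)]
        vseq = dict(viral)[linked]
        if h % 2 == 0 and params.planted_homology_len > 0:
            # plant a homologous region of the linked virus
            hlen = min(params.planted_homology_len, len(vseq))
            start = int(rng.integers(0, len(vseq) - hlen + 1))
            region = _mutate(rng, vseq[start : start + hlen], params.planted_homology_identity)
            ins = int(rng.integers(0, len(genome) - hlen + 1))
            genome = genome[:ins] + region + genome[ins + hlen :]
            truth.host_links.append(
                {"votu_id": linked, "host_id": hid, "mechanism": "homology"}
            )
        else:
            # plant a CRISPR array: repeats interleaved with verbatim spacers
            repeat = _random_seq(rng, params.repeat_len)
            spacers = []
            for _ in range(params.planted_spacers_per_host):
                slen = int(rng.integers(*params.spacer_len_range, endpoint=True))
                sstart = int(rng.integers(0, len(vseq) - slen + 1))
                spacers.append(vseq[sstart : sstart + slen])
            array = repeat + "".join(sp + repeat for sp in spacers)
            ins = int(rng.integers(0, len(genome) - len(array) + 1))
            genome = genome[:ins] + array + genome[ins + len(array) :]
            truth.host_links.append(
                {"votu_id": linked, "host_id": hid, "mechanism": "spacer"}
            )
        hosts.append((hid, genome))
    host_set = SequenceSet(records=hosts)

    sample_ids = [f"virome_{s + 1}" for s in range(params.n_samples)]
    mu, sigma = params.coverage_lognormal
    depth = pd.DataFrame(
        rng.lognormal(mu, sigma, size=(len(viral_set), params.n_samples)),
        index=viral_set.ids,
        columns=sample_ids,
    )
    cov = CoverageTable(
        depth=depth,
        library_bp=pd.Series(params.library_bp, index=sample_ids, dtype=float),
    )
    return viral_set, host_set, cov, truth


def write_amplicon_study(table: OtuTable, truth: GroundTruth, outdir) -> None:
    from .io import write_otu_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_otu_table(
        table,
        outdir / "otu_table.tsv",
        roles_path=outdir / "roles.tsv",
        qpcr_path=outdir / "qpcr.tsv",
    )
    truth.write(outdir / "truth.tsv")


def write_virome_study(
    viral: SequenceSet, hosts: SequenceSet, cov: CoverageTable,
    truth: GroundTruth, outdir,
) -> None:
    from .io import write_coverage_table, write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_fasta(viral, outdir / "viral_contigs.fasta")
    write_fasta(hosts, outdir / "host_genomes.fasta")
    pd.Series(viral.category, name="category").to_csv(
        outdir / "categories.tsv", sep="\t", index_label="contig_id"
    )
    write_coverage_table(cov, outdir / "coverage.tsv")
    truth.write(outdir / "truth.tsv")
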