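"""qPCR-scaled in-silico decontamination of low-biomass amplicon tables.

Background controls sequenced alongside real samples profile the reagent,
air, and instrument contaminants that dominate low-biomass libraries. For
each OTU the R-OTU statistic is the ratio of its mean "absolute" abundance
(relative abundance x per-sample 16S qPCR copy load) in background controls
to that in real ice samples. Genuine ice taxa sit at very low R-OTU because
the controls carry orders of magnitude less template; contaminants carried
into every library at similar absolute load score near or above 1. OTUs with
R-OTU above a small threshold (default 0.01, strict inequality) are treated
as contaminants and removed, after which per-sample proportions are
renormalized.

Also includes the dsDNA copy-number utility used to formulate mock
contaminant spikes from a mass concentration.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import BACKGROUND_CONTROL, ICE_SAMPLE, OtuTable

AVOGADRO = 6.02214076e23
#: Average molar mass of one double-stranded base pair, g/mol.
BP_MOLAR_MASS = 660.0
DEFAULT_THRESHOLD = 0.01


@dataclass
class AbsAbundanceTable:
    """Estimated absolute abundances (16S copies), same axes as the source
    OtuTable; each sample row sums to its qPCR copy load."""

    values: pd.DataFrame  # samples x OTUs
    sample_role: pd.Series
    qpcr_copies: pd.Series


@dataclass
class DecontamResult:
    r_otu: pd.Series  # per-OTU; may contain +inf
    flagged: pd.Series  # per-OTU bool, flagged <=> r_otu > threshold
    threshold: float
    clean_table: OtuTable  # retained OTUs only (controls carried for audit)
    #: Per-ice-sample proportions after removal; in "remove" mode these are
    #: the renormalized retained proportions, in "subtract" mode the
    #: control-implied share was subtracted (floored at 0) first.
    clean_proportions: pd.DataFrame


def absolute_abundance(table: OtuTable) -> AbsAbundanceTable:
    """Scale per-sample relative abundances by the sample's qPCR copy load.

    value[s, o] = (counts[s, o] / sum_o counts[s, o]) * qpcr_copies[s].
    Samples with zero total reads yield all-zero rows (with a warning).
    """
    totals = table.counts.sum(axis=1)
    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        warnings.warn(f"samples with zero reads yield all-zero rows: {empty}")
    rel = table.relative_abundance()
    values = rel.mul(table.qpcr_copies, axis=0)
    return AbsAbundanceTable(
        values=values, sample_role=table.sample_role, qpcr_copies=table.qpcr_copies
    )


def r_otu_values(abs_table: AbsAbundanceTable, per_sample: bool = False) -> pd.Series:
    """R-OTU: mean absolute abundance in controls / mean in ice samples.

    Means are over all samples of each role, zeros included. Conventions:
    0/0 -> 0 (an OTU absent everywhere is not evidence of contamination);
    positive/0 -> +inf (a control-only OTU is a contaminant by definition).

    With ``per_sample=True`` the maximum over per-ice-sample ratios is
    returned instead of the single pooled ratio.
    """
    roles = abs_table.sample_role
    ctrl = roles.index[roles == BACKGROUND_CONTROL]
    ice = roles.index[roles == ICE_SAMPLE]
    if len(ctrl) == 0 or len(ice) == 0:
        raise ValueError("need at least one background control and one ice sample")
    num = abs_table.values.loc[ctrl].mean(axis=0)

    def ratio(den: pd.Series) -> pd.Series:
        with np.errstate(divide="ignore", invalid="ignore"):
            r = num / den
        r[(num == 0) & (den == 0)] = 0.0
        r[(num > 0) & (den == 0)] = np.inf
        return r

    if per_sample:
        per = pd.DataFrame({s: ratio(abs_table.values.loc[s]) for s in ice})
        return per.max(axis=1)
    return ratio(abs_table.values.loc[ice].mean(axis=0))


def remove_contaminants(
    table: OtuTable,
    r: pd.Series,
    threshold: float = DEFAULT_THRESHOLD,
    mode: str = "remove",
) -> DecontamResult:
    """Drop (or proportionally subtract) OTUs whose R-OTU exceeds ``threshold``.

    ``mode="remove"`` (default): flagged OTUs are deleted outright and the
    remaining per-sample proportions renormalized to 1. ``mode="subtract"``:
    for each ice sample the control-implied proportion of every OTU (mean
    control absolute abundance / sample qPCR load) is subtracted from the
    observed proportion, floored at 0, then renormalized; flagged OTUs are
    still deleted. Controls are carried through unmodified (restricted to the
    retained OTU columns) for audit.
    """
    if mode not in ("remove", "subtract"):
        raise ValueError(f"unknown mode {mode!r}")
    missing = set(table.otu_ids) - set(r.index)
    if missing:
        raise ValueError(f"r values missing for OTUs: {sorted(missing)}")
    r = r.reindex(table.otu_ids)
    flagged = r > threshold
    kept = [o for o in table.otu_ids if not flagged[o]]

    clean = table.subset_otus(kept)
    props = clean.relative_abundance().loc[table.ice_samples]

    if mode == "subtract":
        abs_tab = absolute_abundance(table)
        ctrl_mean = abs_tab.values.loc[table.controls].mean(axis=0)
        rel = table.relative_abundance()
        adj = {}
        for s in table.ice_samples:
            load = table.qpcr_copies[s]
            implied = ctrl_mean / load if load > 0 else ctrl_mean * 0.0
            adj[s] = (rel.loc[s] - implied).clip(lower=0.0)
        props = pd.DataFrame(adj).T[kept]
        totals = props.sum(axis=1)
        props = props.div(totals.replace(0, np.nan), axis=0).fillna(0.0)
    else:
        totals = clean.counts.loc[table.ice_samples].sum(axis=1)

    if (totals == 0).any():
        empty = totals.index[totals == 0].tolist()
        warnings.warn(
            f"all OTUs flagged in sample(s) {empty}; retained with zero rows"
        )
    return DecontamResult(
        r_otu=r, flagged=flagged, threshold=threshold,
        clean_table=clean, clean_proportions=props,
    )


def decontaminate(
    table: OtuTable, threshold: float = DEFAULT_THRESHOLD, mode: str = "remove",
    per_sample: bool = False,
) -> DecontamResult:
    """Convenience: absolute abundance -> R-OTU -> removal in one call."""
    r = r_otu_values(absolute_abundance(table), per_sample=per_sample)
    return remove_contaminants(table, r, threshold=threshold, mode=mode)


def dna_copies_per_ul(
    mass_conc_ug_per_ml: float,
    genome_len_bp: float,
    bp_molar_mass: float = BP_MOLAR_MASS,
) -> float:
    """dsDNA copies per microliter from a mass concentration.

    copies/ul = (mass_conc * 1e-9 g/ul per ug/ml)
                / (genome_len * bp_molar_mass / N_A)

    E.g. commercial lambda DNA at 100 ug/ml (genome 48,502 bp) is
    1.88e9 copies/ul.
    """
    if mass_conc_ug_per_ml <= 0 or genome_len_bp <= 0 or bp_molar_mass <= 0:
        raise ValueError("all arguments must be > 0")
    grams_per_ul = mass_conc_ug_per_ml * 1e-9
    grams_per_copy = genome_len_bp * bp_molar_mass / AVOGADRO
    return grams_per_ul / grams_per_copy
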