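import io as _io

import numpy as np
import pandas as pd
import pytest
import skbio

from icecore.io import BACKGROUND_CONTROL, ICE_SAMPLE, OtuTable


def ladder_newick(names, length=1.0):
    """Rooted caterpillar tree over the given leaf names."""
    nwk = f"({names[0]}:{length},{names[1]}:{length})"
    for n in names[2:]:
        nwk = f"({nwk}:{length},{n}:{length})"
    return nwk + ";"


def tree_from_string(nwk: str) -> skbio.TreeNode:
    return skbio.TreeNode.read(_io.StringIO(nwk), convert_underscores=False)


def make_table(counts, roles=None, qpcr=None, taxonomy=None) -> OtuTable:
    """OtuTable from a dict-of-rows {sample: {otu: count}} or DataFrame."""
    df = pd.DataFrame(counts).T if isinstance(counts, dict) else counts
    samples = list(df.index)
    if roles is None:
        roles = {s: ICE_SAMPLE for s in samples}
    if qpcr is None:
        qpcr = {s: 1e6 for s in samples}
    if taxonomy is None:
        taxonomy = {o: "Bacteria" for o in df.columns}
    return OtuTable(
        counts=df,
        taxonomy=pd.Series(taxonomy),
        sample_role=pd.Series(roles),
        qpcr_copies=pd.Series(qpcr, dtype=float),
    )


@pytest.fixture
def toy_table() -> OtuTable:
    """2 ice samples + 2 controls over 4 OTUs with distinct R-OTU regimes."""
    counts = {
        "IceA": {"o1": 80, "o2": 10, "o3": 10, "o4": 0},
        "IceB": {"o1": 70, "o2": 20, "o3": 10, "o4": 0},
        "Ctrl1": {"o1": 0, "o2": 5, "o3": 90, "o4": 5},
        "Ctrl2": {"o1": 0, "o2": 5, "o3": 85, "o4": 10},
    }
    roles = {
        "IceA": ICE_SAMPLE,
        "IceB": ICE_SAMPLE,
        "Ctrl1": BACKGROUND_CONTROL,
        "Ctrl2": BACKGROUND_CONTROL,
    }
    qpcr = {"IceA": 1e6, "IceB": 2e6, "Ctrl1": 1e4, "Ctrl2": 1e4}
    taxonomy = {
        "o1": "Bacteria;Proteobacteria;Beta;Burkholderiales;Oxalobacteraceae;Janthinobacterium",
        "o2": "Bacteria;Proteobacteria;Alpha;Sphingomonadales;Sphingomonadaceae;Sphingomonas",
        "o3": "Bacteria;Firmicutes;Bacilli;Bacillales;Staphylococcaceae;Staphylococcus",
        "o4": "Bacteria;Proteobacteria;Beta;Burkholderiales;Comamonadaceae;unclassified",
    }
    return make_table(counts, roles, qpcr, taxonomy)


def random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=n)])


def mutate(rng: np.random.Generator, seq: str, identity: float) -> str:
    """Substitution-only mutated copy at exactly the requested identity."""
    n_mut = int(round((1 - identity) * len(seq)))
    arr = list(seq)
    for p in rng.choice(len(seq), size=n_mut, replace=False):
        arr[p] = rng.choice([b for b in "ACGT" if b != arr[p]])
    return "".join(arr)
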