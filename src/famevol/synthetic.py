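"""Synthetic data generators and in-text fixtures.

The generators produce inputs with the statistical structure the analyses
assume: per-individual copy numbers whose species medians evolve by the
linear birth-death process down the tree with within-species dispersion
added on top, and per-sample expression values drawn from the stationary-OU
within/between variance model.  Fixtures bundle the values printed in the
study itself: the two calibrated Newick trees, the gene presence/absence
pattern, and the per-species copy-number medians recoverable from the text
(cells the text does not print are left missing, never imputed).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import bdp, eve
from .stats import CopyNumberTable
from .tree import UltrametricTree, parse_newick

__all__ = [
    "SyntheticSpec",
    "generate_cn_dataset",
    "generate_expression_dataset",
    "paper_fixture",
    "TREE6_NEWICK",
    "TREE5_NEWICK",
]

# Calibrated Y-chromosome species trees (branch lengths in ky); the 5-taxon
# tree is the expression tree (single-sample Sumatran orangutan dropped).
TREE6_NEWICK = (
    "((((Bonobo:2432,Chimp:2432):5641,Human:8073):4633,Gorilla:12706):15346.37,"
    "(Borangutan:578,Sorangutan:578):27474.37);"
)
TREE5_NEWICK = (
    "((((Bonobo:2432,Chimp:2432):5641,Human:8073):4633,Gorilla:12706):15351.43,"
    "Borangutan:28057.43);"
)

SPECIES6 = ["Bonobo", "Chimp", "Human", "Gorilla", "Borangutan", "Sorangutan"]
FAMILIES = ["BPY2", "CDY", "DAZ", "HSFY", "PRY", "RBMY", "TSPY", "VCY", "XKRY"]

# ddPCR sample sizes per species in the study.
CN_SAMPLE_SIZES = {
    "Bonobo": 7,
    "Chimp": 9,
    "Human": 10,
    "Gorilla": 14,
    "Borangutan": 7,
    "Sorangutan": 5,
}

# Testis RNA-Seq samples per species (total 12; Sumatran orangutan excluded).
EXPR_SAMPLE_SIZES = {"Bonobo": 2, "Chimp": 2, "Human": 3, "Gorilla": 3, "Borangutan": 2}


@dataclass
class SyntheticSpec:
    """Settings for one synthetic dataset.

    Defaults mirror the study conditions: the printed 6-taxon tree, nine
    families evolving at lambda = 0.05 events per gene per My, the study's
    per-species ddPCR sample sizes, and a per-family overdispersion factor
    for individual-level measurement noise.
    """

    tree: UltrametricTree = field(default_factory=lambda: parse_newick(TREE6_NEWICK))
    lambda_: float = 0.05
    n_families: int = 9
    root_range: tuple[int, int] = (1, 40)
    dispersion: float = 0.5
    individuals_per_species: dict[str, int] = field(
        default_factory=lambda: dict(CN_SAMPLE_SIZES)
    )
    eve_params: dict[str, eve.EVEParams] = field(
        default_factory=lambda: {
            f: eve.EVEParams(theta=2.0, alpha=0.5, sigma2=0.3, beta=0.5)
            for f in ["BPY2", "CDY", "DAZ", "RBMY", "TSPY"]
        }
    )
    samples_per_species: dict[str, int] = field(
        default_factory=lambda: dict(EXPR_SAMPLE_SIZES)
    )
    seed: int = 0

    def __post_init__(self):
        if self.lambda_ < 0 or self.dispersion < 0:
            raise ValueError("rates and dispersion must be non-negative")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


def generate_cn_dataset(spec: SyntheticSpec):
    """Copy-number table plus ground truth.

    Species-level counts are simulated with the birth-death kernel down the
    tree; each individual's value is the species count plus rounded Gaussian
    noise with variance dispersion * count, floored at zero.  Returns
    (CopyNumberTable, true species counts DataFrame, true ancestral counts).
    """
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.root_range
    max_root = hi
    model = bdp.BDPModel(spec.lambda_, bdp.default_n_max(2 * max_root), max_root)
    # root sampled uniformly on root_range via the model prior restricted below
    profiles = []
    truth_anc = {}
    cache = bdp._MatrixCache(model.lambda_, model.n_max)
    states = np.arange(model.n_max + 1)
    fam_names = (
        FAMILIES[: spec.n_families]
        if spec.n_families <= len(FAMILIES)
        else [f"fam{i}" for i in range(spec.n_families)]
    )
    for i in range(spec.n_families):
        counts: dict = {}
        assign: dict = {}
        anc: dict[str, int] = {}
        for node in spec.tree.preorder():
            if node is spec.tree.root:
                assign[node] = int(rng.integers(lo, hi + 1))
            else:
                row = cache.get(node.edge.length)[assign[node.parent_node]]
                assign[node] = int(rng.choice(states, p=row / row.sum()))
            if node.is_leaf():
                counts[node.taxon.label] = assign[node]
            else:
                anc[spec.tree.label_of(node)] = assign[node]
        name = fam_names[i]
        profiles.append((name, counts))
        truth_anc[name] = anc
    true_counts = pd.DataFrame(
        {name: pd.Series(counts) for name, counts in profiles}
    )
    rows = []
    species = []
    ids = []
    for sp in spec.tree.tip_labels:
        for j in range(spec.individuals_per_species[sp]):
            vals = {}
            for name, counts in profiles:
                c = counts[sp]
                sd = np.sqrt(spec.dispersion * c) if c > 0 else 0.0
                noisy = c + rng.normal(0.0, sd) if sd > 0 else float(c)
                vals[name] = max(float(np.floor(noisy + 0.5)), 0.0)
            rows.append(vals)
            species.append(sp)
            ids.append(f"{sp}_{j}")
    table = CopyNumberTable(
        pd.DataFrame(rows, index=ids), pd.Series(species, index=ids, name="species")
    )
    return table, true_counts, truth_anc


def generate_expression_dataset(spec: SyntheticSpec, tree: UltrametricTree | None = None):
    """Expression matrix drawn from the EVE model; returns (matrix, params)."""
    tr = tree if tree is not None else parse_newick(TREE5_NEWICK)
    mat = eve.simulate_expression(tr, spec.eve_params, spec.samples_per_species, spec.seed)
    return mat, dict(spec.eve_params)


# ---------------------------------------------------------------------------
# fixtures printed in the study text
# ---------------------------------------------------------------------------

def _gene_presence() -> pd.DataFrame:
    """Presence (1) / absence-or-pseudogenized (0) per species and family."""
    present = pd.DataFrame(1, index=SPECIES6, columns=FAMILIES)
    for fam in ["HSFY", "PRY", "XKRY"]:  # pseudogenized in Pan
        present.loc[["Bonobo", "Chimp"], fam] = 0
    present.loc[["Bonobo", "Gorilla", "Borangutan", "Sorangutan"], "VCY"] = 0
    return present


def _median_table() -> pd.DataFrame:
    """Per-species copy-number medians printed in the study text.

    Cells not printed are NaN.  Pseudogenized/absent families carry zeros.
    """
    nan = np.nan
    data = {
        #            Bonobo Chimp Human Gorilla Borang Sorang
        "BPY2": [1, 2, nan, nan, nan, nan],
        "CDY": [3, 5, nan, nan, nan, nan],
        "DAZ": [2, 4, nan, nan, nan, nan],
        "HSFY": [0, 0, 2, nan, nan, nan],
        "PRY": [0, 0, 2, 2, 8, 10],
        "RBMY": [29, 11, nan, nan, nan, nan],
        "TSPY": [48, 18, nan, 6, 32, 23],
        "VCY": [0, 2, 2, 0, 0, 0],
        "XKRY": [0, 0, 2, 2, 15, 22],
    }
    return pd.DataFrame(data, index=SPECIES6)


def paper_fixture(name: str):
    """Objects embedding values printed in the study.

    Known names: "tree6" and "tree5" (calibrated Newick trees),
    "medians" (partial per-species median table, unprinted cells NaN),
    "gene_presence" (presence/absence matrix).
    """
    fixtures = {
        "tree6": lambda: parse_newick(TREE6_NEWICK),
        "tree5": lambda: parse_newick(TREE5_NEWICK),
        "medians": _median_table,
        "gene_presence": _gene_presence,
    }
    if name not in fixtures:
        raise KeyError(f"unknown fixture {name!r}; available: {sorted(fixtures)}")
    return fixtures[name]()
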