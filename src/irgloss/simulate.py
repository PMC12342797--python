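"""Synthetic pipeline inputs with known ground truth.

Every downstream stage of the analysis — domain-rule classification,
repertoire difference testing, syntenic gene-loss accounting and PGLS —
can be exercised end to end on data generated here, with the generating
parameters retained so that tests can check recovery.

What is emulated, and what is not: the generator produces the *tabular
shapes* the pipeline consumes (per-species domain-annotation tables,
outgroup-referenced pan-gene presence/absence matrices, a crop trait
table, a newick phylogeny), not sequences or annotation noise.  Domain
architectures are drawn noise-free from fixed per-class templates, so a
correct classifier recovers the intended labels exactly; orthogroup
absences are independent Bernoulli events; the PGLS response is a linear
signal plus multivariate-normal Brownian noise on the supplied tree.

A single integer seed governs everything; each table draws from a
deterministic substream derived from (seed, purpose, index), so partial
reruns reproduce bytes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .classify import IRG_CLASSES, IRGClass
from .geneloss import PanGeneMatrix
from .pgls import bm_covariance

__all__ = [
    "SimConfig",
    "ARCHITECTURE_TEMPLATES",
    "DECOY_ARCHITECTURES",
    "DEFAULT_CLASS_FREQUENCIES",
    "generate_domain_tables",
    "generate_pangene_matrix",
    "generate_pgls_dataset",
    "random_tree",
]

#: Noise-free architecture templates realising each IRG class.  Each entry
#: is a tuple of variants; every variant classifies to its key under the
#: precedence ladder (verified by the round-trip tests).
ARCHITECTURE_TEMPLATES: dict[IRGClass, tuple[tuple[str, ...], ...]] = {
    IRGClass.CNL: (("CC", "NBS", "LRR"), ("CC", "NBS", "LRR", "LRR")),
    IRGClass.CN: (("CC", "NBS"),),
    IRGClass.NL: (("NBS", "LRR"), ("NBS", "LRR", "LRR")),
    IRGClass.N: (("NBS",), ("NBS", "OTHER")),
    IRGClass.TNL: (("TIR", "NBS", "LRR"),),
    IRGClass.TN: (("TIR", "NBS"),),
    IRGClass.CTNL: (("CC", "TIR", "NBS", "LRR"), ("TIR", "CC", "NBS", "LRR")),
    IRGClass.TIR_X: (("TIR", "OTHER"), ("TIR", "LRR"), ("TIR", "KINASE")),
    IRGClass.RPW8_X: (("RPW8", "NBS", "LRR"), ("RPW8", "CC")),
    IRGClass.LRR_RLK: (("LRR", "TM", "KINASE"), ("LRR", "LRR", "TM", "KINASE")),
    IRGClass.LRR_RLP: (("LRR", "TM"), ("LRR", "LRR", "TM")),
    IRGClass.LYK: (("LYSM", "TM", "KINASE"), ("LYSM", "LYSM", "TM", "KINASE")),
    IRGClass.LYP: (("LYSM", "TM"), ("LYSM", "LYSM", "TM")),
    IRGClass.LECRK: (("LECTIN", "TM", "KINASE"),),
}

#: Decoy architectures for non-IRG proteins; each matches no rule
#: (kinase-only, bare LRR without TM, etc.), keeping negatives unambiguous.
DECOY_ARCHITECTURES: tuple[tuple[str, ...], ...] = (
    ("KINASE",),
    ("LRR",),
    ("OTHER",),
    ("TM", "KINASE"),
    ("LECTIN", "TM"),
    ("CC",),
    ("LECTIN", "KINASE"),
    ("OTHER", "OTHER", "KINASE"),
)

#: Default expected per-class proportions of a plant proteome.  Roughly
#: 2–3% of genes are immune receptors, dominated by NLRs and LRR-kinases;
#: the remainder of each proteome is decoy (non-IRG) architectures.
DEFAULT_CLASS_FREQUENCIES: dict[IRGClass, float] = {
    IRGClass.CNL: 0.0045,
    IRGClass.CN: 0.0010,
    IRGClass.NL: 0.0030,
    IRGClass.N: 0.0012,
    IRGClass.TNL: 0.0020,
    IRGClass.TN: 0.0006,
    IRGClass.CTNL: 0.0003,
    IRGClass.TIR_X: 0.0010,
    IRGClass.RPW8_X: 0.0004,
    IRGClass.LRR_RLK: 0.0060,
    IRGClass.LRR_RLP: 0.0035,
    IRGClass.LYK: 0.0006,
    IRGClass.LYP: 0.0006,
    IRGClass.LECRK: 0.0025,
}


@dataclass
class SimConfig:
    """Parameters of the synthetic study.

    Defaults emulate the shape of the real study: 15 crop/wild/outgroup
    triplicates, proteomes of a few thousand genes with ~2.7% immune
    receptors, per-orthogroup background loss rates of a few percent with
    an additive IRG-specific excess in crops, and a Brownian trait model
    on the crop phylogeny.
    """

    seed: int = 0
    n_species: int = 15
    n_proteins_per_species: int = 5000
    class_frequencies: dict[IRGClass, float] = field(
        default_factory=lambda: dict(DEFAULT_CLASS_FREQUENCIES)
    )
    crop_loss_rate: float = 0.03
    wild_loss_rate: float = 0.03
    irg_extra_loss: float = 0.02
    n_orthogroups: int = 20000
    pgls_slope: float = 0.0005
    pgls_sigma2: float = 0.25
    #: multiplies crop-side class frequencies (1.0 = null, <1 = reduced
    #: crop repertoire); extension knob for power and end-to-end demos.
    crop_repertoire_scale: float = 1.0

    def __post_init__(self) -> None:
        freqs = {}
        for k, v in self.class_frequencies.items():
            try:
                kc = IRGClass(k)
            except ValueError:
                raise ValueError(f"unknown IRG class in class_frequencies: {k!r}")
            if kc is IRGClass.NONE:
                raise ValueError("class_frequencies must not name NONE")
            if not 0 <= v <= 1:
                raise ValueError(f"frequency for {kc} outside [0, 1]")
            freqs[kc] = float(v)
        if sum(freqs.values()) > 1 + 1e-12:
            raise ValueError("class frequencies must sum to <= 1")
        self.class_frequencies = freqs
        for name in ("crop_loss_rate", "wild_loss_rate", "irg_extra_loss"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        for name in ("n_species", "n_proteins_per_species", "n_orthogroups"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.pgls_sigma2 < 0:
            raise ValueError("pgls_sigma2 must be >= 0")
        if not 0 <= self.crop_repertoire_scale:
            raise ValueError("crop_repertoire_scale must be >= 0")


def _substream(seed: int, *keys: int) -> np.random.Generator:
    """Deterministic child generator keyed on (seed, purpose, index...)."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=tuple(keys)))


# purpose codes for substreams
_DOMAINS, _PANGENE, _PGLS, _TREE = 1, 2, 3, 4


def _sample_proteome(
    rng: np.random.Generator,
    species_id: str,
    n: int,
    freqs: dict[IRGClass, float],
) -> pd.DataFrame:
    classes = list(freqs)
    probs = np.array([freqs[c] for c in classes], dtype=float)
    p_none = 1.0 - probs.sum()
    draw = rng.choice(len(classes) + 1, size=n, p=np.append(probs, p_none))
    rows = []
    for i, idx in enumerate(draw):
        if idx < len(classes):
            cls = classes[idx]
            variants = ARCHITECTURE_TEMPLATES[cls]
        else:
            cls = IRGClass.NONE
            variants = DECOY_ARCHITECTURES
        arch = variants[rng.integers(len(variants))]
        rows.append(
            (f"{species_id}_p{i:06d}", species_id, ",".join(arch), cls.value)
        )
    return pd.DataFrame(
        rows, columns=["protein_id", "species_id", "domains", "true_class"]
    )


def generate_domain_tables(cfg: SimConfig) -> dict[str, pd.DataFrame]:
    """Per-species domain-annotation tables for crops and wild relatives.

    Returns a dict mapping species id (``crop_XX`` / ``wild_XX``) to a
    frame with columns ``protein_id``, ``species_id``, ``domains``
    (comma-separated ordered tokens) and ``true_class`` — the intended
    label, kept as hidden truth for round-trip tests (the pipeline reader
    drops it).
    """
    crop_freqs = {
        c: min(1.0, v * cfg.crop_repertoire_scale)
        for c, v in cfg.class_frequencies.items()
    }
    if sum(crop_freqs.values()) > 1:
        raise ValueError("scaled crop class frequencies exceed 1")
    tables: dict[str, pd.DataFrame] = {}
    for i in range(cfg.n_species):
        for role, freqs in (("crop", crop_freqs), ("wild", cfg.class_frequencies)):
            sp = f"{role}_{i:02d}"
            rng = _substream(cfg.seed, _DOMAINS, i, 0 if role == "crop" else 1)
            tables[sp] = _sample_proteome(
                rng, sp, cfg.n_proteins_per_species, freqs
            )
    return tables


def generate_pangene_matrix(
    cfg: SimConfig,
    irg_flags: np.ndarray,
    triplicate_index: int = 0,
) -> tuple[PanGeneMatrix, dict[str, float]]:
    """One triplicate's outgroup-referenced presence/absence matrix.

    Every orthogroup carries an outgroup reference gene.  Crop absence is
    Bernoulli(crop_loss_rate + irg_extra_loss·is_irg); wild absence is
    Bernoulli(wild_loss_rate), independently.  Returns the matrix and the
    true per-category rates used (hidden truth).
    """
    irg_flags = np.asarray(irg_flags, dtype=bool)
    if irg_flags.size != cfg.n_orthogroups:
        raise ValueError(
            f"irg_flags length {irg_flags.size} != n_orthogroups {cfg.n_orthogroups}"
        )
    rng = _substream(cfg.seed, _PANGENE, triplicate_index)
    crop_rate = np.where(
        irg_flags,
        np.minimum(1.0, cfg.crop_loss_rate + cfg.irg_extra_loss),
        cfg.crop_loss_rate,
    )
    crop_absent = rng.random(cfg.n_orthogroups) < crop_rate
    wild_absent = rng.random(cfg.n_orthogroups) < cfg.wild_loss_rate
    tid = f"trip_{triplicate_index:02d}"
    table = pd.DataFrame(
        {
            "orthogroup_id": [f"{tid}_og{k:06d}" for k in range(cfg.n_orthogroups)],
            "crop": ~crop_absent,
            "wild": ~wild_absent,
            "outgroup": np.ones(cfg.n_orthogroups, dtype=bool),
            "outgroup_gene_id": [
                f"out_{triplicate_index:02d}_g{k:06d}" for k in range(cfg.n_orthogroups)
            ],
            "is_irg": irg_flags,
        }
    )
    matrix = PanGeneMatrix(
        triplicate_id=tid,
        crop_species=f"crop_{triplicate_index:02d}",
        wild_species=f"wild_{triplicate_index:02d}",
        outgroup_species=f"outgroup_{triplicate_index:02d}",
        table=table,
    )
    truth = {
        "crop_loss_rate_irg": float(min(1.0, cfg.crop_loss_rate + cfg.irg_extra_loss)),
        "crop_loss_rate_background": float(cfg.crop_loss_rate),
        "wild_loss_rate": float(cfg.wild_loss_rate),
    }
    return matrix, truth


def random_tree(
    n_tips: int, seed: int, labels: list[str] | None = None
) -> dendropy.Tree:
    """Random rooted binary tree with exponential branch lengths.

    Built by iteratively joining random subtree pairs (a simple
    coalescent-style construction); adequate as a test phylogeny, not a
    model of any particular diversification process.
    """
    if labels is None:
        labels = [f"t{i}" for i in range(n_tips)]
    if len(labels) != n_tips:
        raise ValueError("labels length must equal n_tips")
    rng = _substream(seed, _TREE)
    taxa = dendropy.TaxonNamespace(labels)
    nodes = []
    for lab in labels:
        nd = dendropy.Node(taxon=taxa.get_taxon(lab))
        nd.edge.length = float(rng.exponential(1.0))
        nodes.append(nd)
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[int(i)], nodes[int(j)]
        parent = dendropy.Node()
        parent.add_child(a)
        parent.add_child(b)
        parent.edge.length = float(rng.exponential(1.0))
        nodes = [nd for k, nd in enumerate(nodes) if k not in (int(i), int(j))]
        nodes.append(parent)
    root = nodes[0]
    root.edge.length = 0.0
    tree = dendropy.Tree(taxon_namespace=taxa)
    tree.seed_node = root
    tree.is_rooted = True
    return tree


def generate_pgls_dataset(
    cfg: SimConfig,
    tree: dendropy.Tree,
    predictor_values: dict[str, float],
    intercept: float = 0.0,
    extra_predictors: pd.DataFrame | None = None,
    replicate: int = 0,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Trait table with response = intercept + slope·predictor + BM noise.

    ``predictor_values`` maps tree tip labels to the driving predictor;
    noise is multivariate normal with covariance pgls_sigma2 · C(tree).
    ``extra_predictors`` (indexed by tip label) are appended unchanged,
    e.g. pure-noise covariates for specificity checks.  Returns the table
    and the generating truth.
    """
    tips = sorted(predictor_values)
    tree_tips = {lf.taxon.label for lf in tree.leaf_node_iter()}
    missing = [t for t in tips if t not in tree_tips]
    if missing:
        raise ValueError(f"predictor tips not in tree: {missing}")
    C = bm_covariance(tree, tips)
    if np.any(np.diag(C) <= 0):
        raise ValueError("tree has zero root-to-tip distance for some tip")
    x = np.array([predictor_values[t] for t in tips], dtype=float)
    mean = intercept + cfg.pgls_slope * x
    rng = _substream(cfg.seed, _PGLS, replicate)
    if cfg.pgls_sigma2 > 0:
        L = np.linalg.cholesky(cfg.pgls_sigma2 * C + 1e-12 * np.eye(len(tips)))
        noise = L @ rng.standard_normal(len(tips))
    else:
        noise = np.zeros(len(tips))
    table = pd.DataFrame(
        {"crop_id": tips, "predictor": x, "response": mean + noise}
    )
    if extra_predictors is not None:
        extra = extra_predictors.loc[tips].reset_index(drop=True)
        table = pd.concat([table, extra], axis=1)
    truth = {
        "slope": float(cfg.pgls_slope),
        "intercept": float(intercept),
        "sigma2": float(cfg.pgls_sigma2),
    }
    return table, truth
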