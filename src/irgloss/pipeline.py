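"""End-to-end orchestration of the four analysis stages.

``run_pipeline`` executes classification → repertoire testing → gene-loss
accounting → PGLS in order, skipping stages whose inputs are absent, and
writes each stage's outputs to its own subdirectory plus a manifest
recording the configuration hash, seed, and per-stage row counts.  A
fixed configuration and seed yield byte-identical output trees.

Inputs may be real files (domain TSVs, pan-gene TSVs, trait CSV, newick
tree) or a :class:`~irgloss.simulate.SimConfig`, in which case the
synthetic generator first materialises the same file formats under
``simulate/``.
"""

from __future__ import annotations

import hashlib
import json
import logging
from contextlib import contextmanager
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as pio
from .classify import classify_proteome
from .geneloss import (
    contrast_crop_vs_wild,
    contrast_irg_vs_genomewide,
    loss_proportions,
    score_losses,
)
from .pgls import run_pgls_suite
from .repertoire import Scope, bh_adjust, compare_repertoires
from .simulate import (
    SimConfig,
    generate_domain_tables,
    generate_pangene_matrix,
    generate_pgls_dataset,
    random_tree,
)

__all__ = ["RunConfig", "StageError", "run_pipeline"]

log = logging.getLogger("irgloss.pipeline")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@contextmanager
def _stage(name: str):
    try:
        yield
    except (StageError, KeyboardInterrupt):
        raise
    except pio.FormatError:
        raise  # already carries file context
    except Exception as exc:
        raise StageError(name, exc) from exc


@dataclass
class RunConfig:
    """What to run and where.

    Either real-input paths or a ``sim`` config must be present.  With
    ``bh_family="per-scope"`` the BH correction family is the set of
    crops within each scope (the default); ``"joint"`` pools all scopes
    into one family.
    """

    out_dir: str
    domain_tables: list[str] = field(default_factory=list)
    pangene_tables: list[str] = field(default_factory=list)
    trait_table: str | None = None
    tree: str | None = None
    sim: SimConfig | None = None
    scopes: list[str] = field(default_factory=lambda: ["full", "nlr", "prr"])
    bh_family: str = "per-scope"
    shapiro_threshold: float = 0.05
    seed: int = 0
    tip_rename: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        has_real = bool(self.domain_tables or self.pangene_tables or self.trait_table)
        if not has_real and self.sim is None:
            raise ValueError("RunConfig needs input paths or a SimConfig")
        if not 0 < self.shapiro_threshold < 1:
            raise ValueError("shapiro_threshold must lie in (0, 1)")
        if self.bh_family not in ("per-scope", "joint"):
            raise ValueError("bh_family must be 'per-scope' or 'joint'")


def _config_hash(cfg: RunConfig) -> str:
    # where the run writes is not part of what it computes
    d = asdict(cfg)
    d.pop("out_dir")
    if cfg.sim is not None:
        d["sim"]["class_frequencies"] = {
            k.value: v for k, v in cfg.sim.class_frequencies.items()
        }
    blob = json.dumps(d, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()


def _materialise_synthetic(cfg: RunConfig, out: Path) -> None:
    """Generate synthetic inputs and point cfg's paths at them."""
    sim = cfg.sim
    sim_dir = out / "simulate"
    sim_dir.mkdir(parents=True, exist_ok=True)
    tables = generate_domain_tables(sim)
    for sp, df in sorted(tables.items()):
        p = sim_dir / f"domains_{sp}.tsv"
        pio.write_domain_table(df, p)
        cfg.domain_tables.append(str(p))

    rng = np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=(99,)))
    irg_frac = sum(sim.class_frequencies.values())
    for i in range(sim.n_species):
        flags = rng.random(sim.n_orthogroups) < max(irg_frac, 0.01)
        m, _ = generate_pangene_matrix(sim, flags, triplicate_index=i)
        p = sim_dir / f"pangene_{m.triplicate_id}.tsv"
        pio.write_pangene_matrix(m, p)
        cfg.pangene_tables.append(str(p))

    crop_ids = [f"crop_{i:02d}" for i in range(sim.n_species)]
    tree = random_tree(sim.n_species, sim.seed, labels=crop_ids)
    tree_path = sim_dir / "crops.nwk"
    tree.write(path=str(tree_path), schema="newick", suppress_rooting=True)
    cfg.tree = str(tree_path)

    pred_rng = np.random.default_rng(np.random.SeedSequence(sim.seed, spawn_key=(98,)))
    # years since domestication, order 10^3-10^4: matches the slope's units
    predictor = {c: float(pred_rng.uniform(1000, 12000)) for c in crop_ids}
    table, _ = generate_pgls_dataset(sim, tree, predictor)
    table = table.rename(columns={"predictor": "time_since_domestication"})
    extra = pred_rng.standard_normal((sim.n_species, 2))
    table["life_history"] = (pred_rng.random(sim.n_species) < 0.5).astype(int)
    table["assembly_genome_size"] = 400 + 200 * extra[:, 0]
    table["min_crop_cycle"] = 120 + 40 * extra[:, 1]
    trait_path = sim_dir / "traits.csv"
    pio.write_trait_table(table, trait_path)
    cfg.trait_table = str(trait_path)


def run_pipeline(cfg: RunConfig) -> dict:
    """Run all applicable stages; returns the manifest dict."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "stages": {},
    }

    if cfg.sim is not None:
        with _stage("simulate"):
            _materialise_synthetic(cfg, out)
        manifest["stages"]["simulate"] = {
            "domain_tables": len(cfg.domain_tables),
            "pangene_tables": len(cfg.pangene_tables),
        }
        log.info("simulate: %d domain tables, %d pan-gene tables",
                 len(cfg.domain_tables), len(cfg.pangene_tables))

    counts = []
    if cfg.domain_tables:
        stage = out / "classify"
        stage.mkdir(exist_ok=True)
        for path in cfg.domain_tables:
            with _stage("classify"):
                archs = pio.read_domain_table(path)
                # prefer the species_id column, fall back to the file stem
                df = pd.read_csv(path, sep="\t", dtype=str)
                if "species_id" in df.columns and len(df):
                    species = df["species_id"].iloc[0]
                else:
                    species = Path(path).stem
                counts.append(classify_proteome(archs, species))
        pio.write_repertoire_counts(counts, stage / "repertoire_counts.tsv")
        manifest["stages"]["classify"] = {
            "proteomes": len(counts),
            "irg_total": int(sum(rc.total for rc in counts)),
        }
        log.info("classify: %d proteomes", len(counts))

    if counts:
        by_sp = {rc.species_id: rc for rc in counts}
        crop_ids = sorted(s for s in by_sp if s.startswith("crop"))
        pairs = []
        for cid in crop_ids:
            wid = cid.replace("crop", "wild", 1)
            if wid not in by_sp:
                raise ValueError(f"crop {cid} has no paired wild species {wid}")
            pairs.append((by_sp[cid], by_sp[wid]))
        if pairs:
            stage = out / "repertoire"
            stage.mkdir(exist_ok=True)
            all_results = []
            with _stage("repertoire"):
                for scope in cfg.scopes:
                    all_results.extend(
                        compare_repertoires(pairs, Scope(scope), cfg.shapiro_threshold)
                    )
            if cfg.bh_family == "joint":
                adj = bh_adjust([r.p_raw for r in all_results])
                for r, a in zip(all_results, adj):
                    r.p_adjusted = float(a)
            df = pd.DataFrame(
                {
                    "crop": [r.crop_id for r in all_results],
                    "scope": [r.scope.value for r in all_results],
                    "test": [r.test_used for r in all_results],
                    "shapiro_p": [r.shapiro_p for r in all_results],
                    "statistic": [r.statistic for r in all_results],
                    "p_raw": [r.p_raw for r in all_results],
                    "p_adjusted": [r.p_adjusted for r in all_results],
                }
            )
            pio.write_results(df, stage / "repertoire_tests.tsv")
            manifest["stages"]["repertoire"] = {"tests": len(all_results)}
            log.info("repertoire: %d tests", len(all_results))

    if cfg.pangene_tables:
        stage = out / "geneloss"
        stage.mkdir(exist_ok=True)
        crop_sums, wild_sums = [], []
        for path in cfg.pangene_tables:
            m = pio.read_pangene_matrix(path)
            with _stage("geneloss"):
                ev = score_losses(m)
                cs, ws = loss_proportions(ev, m)
            crop_sums.append(cs)
            wild_sums.append(ws)
        pio.write_loss_summaries(crop_sums + wild_sums, stage / "loss_summary.tsv")
        contrasts = {}
        if len(crop_sums) >= 2:
            with _stage("geneloss"):
                paired = contrast_irg_vs_genomewide(crop_sums, cfg.shapiro_threshold)
                welch = contrast_crop_vs_wild(crop_sums, wild_sums)
            contrasts = {
                "irg_vs_genomewide": vars(paired),
                "crop_vs_wild": vars(welch),
            }
            (stage / "contrasts.json").write_text(
                json.dumps(contrasts, indent=2, sort_keys=True) + "\n"
            )
        manifest["stages"]["geneloss"] = {
            "triplicates": len(crop_sums),
            "contrasts": sorted(contrasts),
        }
        log.info("geneloss: %d triplicates", len(crop_sums))

    if cfg.trait_table and cfg.tree:
        stage = out / "pgls"
        stage.mkdir(exist_ok=True)
        table = pio.read_trait_table(cfg.trait_table)
        tree = pio.read_newick(cfg.tree)
        with _stage("pgls"):
            suite = run_pgls_suite(
                table, tree, tip_rename=cfg.tip_rename or None
            )
        frames = [suite.bivariate_frame()]
        mv = suite.multivariate.to_frame()
        mv.insert(0, "model", "multivariate")
        frames.append(mv)
        pio.write_results(pd.concat(frames, ignore_index=True), stage / "coefficients.tsv")
        if suite.vif:
            vif_df = pd.DataFrame(
                sorted(suite.vif.items()), columns=["predictor", "vif"]
            )
            pio.write_results(vif_df, stage / "vif.tsv")
        manifest["stages"]["pgls"] = {
            "bivariate_models": len(suite.bivariate),
            "rows": len(table),
        }
        log.info("pgls: %d bivariate models over %d rows", len(suite.bivariate), len(table))
    elif cfg.trait_table or cfg.tree:
        log.info("pgls: skipped (need both trait table and tree)")

    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n"
    )
    return manifest
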