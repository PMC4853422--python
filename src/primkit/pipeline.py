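"""Configuration-driven orchestration of every analysis stage.

``run_pipeline`` executes, in order: promoters -> states -> prim ->
expression -> transitions -> enhancers -> profiles, persisting every stage
output as TSV/BED under the output directory and writing a machine-readable
``summary.json`` (state counts, cutoffs, PCA variance fractions, transition
category counts, enhancer subset sizes, profile cluster sizes). Stages read
their inputs from the persisted intermediates when re-run individually, so a
single-stage re-run reproduces the full-run result for that stage. Stages
whose inputs are absent from the configuration (no K27ac samples, no
expression table) are skipped with an explicit notice.

``write_study`` emits a SyntheticStudy in the same standard formats the
pipeline reads (BED, bedGraph, refFlat-like TSV, expression TSV) plus the
ground-truth tables and a ready-to-run YAML configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import sys
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from . import dynamics, enhancers as enh, expression as expr_mod, profiles as prof
from .intervals import (
    GenomeLayout,
    PeakSet,
    load_coverage,
    parse_annotation,
    parse_bed,
    write_annotation,
    write_bed,
    write_bedgraph,
)
from .promoters import (
    PromoterSet,
    STATE_DTYPE,
    build_prim_table,
    call_promoter_state,
    consensus_bivalent_genes,
    consensus_state,
    define_promoters,
    promoter_signal_column,
)
from .simulate import SyntheticStudy

log = logging.getLogger("primkit")

STAGES = (
    "promoters", "states", "prim", "expression", "transitions",
    "enhancers", "profiles",
)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass
class PipelineConfig:
    genome: str
    annotation: str
    samples: str
    outdir: str
    annotation_dialect: str = "refflat"
    expression: str | None = None
    expression_groups: str | None = None
    flank: int = 2000
    pseudocount: float = 0.001
    min_support: int = 2
    merge_gap: int = 500
    k4_extension: int = 1000
    annotation_window: int = 100_000
    fc_threshold: float = 1.0
    alpha: float = 0.05
    bin_width: int = 100
    half_width: int = 2000
    k: int = 2
    seed: int = 0
    restarts: int = 100
    k4_union: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=True)


def _digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()[:12]


class _Context:
    """Lazy loader over the config's inputs and the persisted intermediates."""

    def __init__(self, config: PipelineConfig):
        self.config = config
        self.out = Path(config.outdir)
        self.cache: dict[str, object] = {}
        self.manifest = pd.read_csv(
            config.samples, sep="\t", dtype={"sample_id": str, "cell_type": str}
        )

    # ---- raw inputs -------------------------------------------------
    @property
    def layout(self) -> GenomeLayout:
        if "layout" not in self.cache:
            self.cache["layout"] = GenomeLayout.from_tsv(self.config.genome)
        return self.cache["layout"]

    @property
    def annotation(self):
        if "annotation" not in self.cache:
            self.cache["annotation"] = parse_annotation(
                self.config.annotation, self.config.annotation_dialect, self.layout
            )
        return self.cache["annotation"]

    @property
    def promoters(self) -> PromoterSet:
        if "promoters" not in self.cache:
            self.cache["promoters"] = define_promoters(
                self.annotation, self.config.flank, self.layout
            )
        return self.cache["promoters"]

    def chip_rows(self) -> pd.DataFrame:
        return self.manifest[self.manifest["mark"].isin(["K4me3", "K27me3"])]

    def k27ac_rows(self) -> pd.DataFrame:
        return self.manifest[self.manifest["mark"] == "K27ac"]

    def sample_groups(self) -> dict[str, str]:
        rows = self.chip_rows()
        return dict(zip(rows["sample_id"], rows["cell_type"]))

    # ---- persisted intermediates ------------------------------------
    def frame(self, name: str, **kw) -> pd.DataFrame:
        if name not in self.cache:
            path = self.out / f"{name}.tsv"
            if not path.exists():
                raise PipelineError(
                    f"intermediate {path.name} missing; run its stage first"
                )
            self.cache[name] = pd.read_csv(path, sep="\t", index_col=0, **kw)
        return self.cache[name]

    def put(self, name: str, frame: pd.DataFrame) -> None:
        self.cache[name] = frame
        frame.to_csv(self.out / f"{name}.tsv", sep="\t")

    def states_frame(self, name: str) -> pd.DataFrame:
        df = self.frame(name)
        return df.astype("float").astype(STATE_DTYPE)


def _setup_logging(outdir: Path) -> None:
    log.setLevel(logging.INFO)
    log.handlers.clear()
    stream = logging.StreamHandler(sys.stderr)
    filehandler = logging.FileHandler(outdir / "run.log", mode="a")
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(message)s")
    for h in (stream, filehandler):
        h.setFormatter(fmt)
        log.addHandler(h)


# ---------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------

def _stage_promoters(ctx: _Context, summary: dict) -> None:
    promoters = ctx.promoters
    rows = [
        {
            "gene": p.gene_id,
            "chrom": p.interval.chrom,
            "start": p.interval.start,
            "end": p.interval.end,
            "tss": p.tss,
            "strand": p.strand,
        }
        for p in promoters.values()
    ]
    ctx.put("promoter_table", pd.DataFrame(rows).set_index("gene"))
    write_bed(
        promoters.intervals(),
        ctx.out / "promoters.bed",
        names=promoters.genes,
    )
    summary["n_genes"] = len(promoters)


def _stage_states(ctx: _Context, summary: dict) -> None:
    promoters = ctx.promoters
    chip = ctx.chip_rows()
    states, k4_sig, k27_sig = {}, {}, {}
    for sample_id, rows in chip.groupby("sample_id", sort=True):
        by_mark = {r.mark: r for r in rows.itertuples()}
        if "K4me3" not in by_mark or "K27me3" not in by_mark:
            raise PipelineError(f"sample {sample_id} lacks a K4me3 or K27me3 file")
        ct = by_mark["K4me3"].cell_type
        k4 = parse_bed(by_mark["K4me3"].peaks, "K4me3", sample_id, ct)
        k27 = parse_bed(by_mark["K27me3"].peaks, "K27me3", sample_id, ct)
        states[sample_id] = call_promoter_state(promoters, k4, k27)
        for mark, store in (("K4me3", k4_sig), ("K27me3", k27_sig)):
            row = by_mark[mark]
            track = load_coverage(
                row.coverage, sample_id, mark, int(row.library_size)
            )
            store[sample_id] = promoter_signal_column(track, promoters)
    state_df = pd.DataFrame(states)
    ctx.put("states", state_df)
    ctx.put("signals_k4", pd.DataFrame(k4_sig))
    ctx.put("signals_k27", pd.DataFrame(k27_sig))
    groups = ctx.sample_groups()
    cons, bivalent_counts, fractions = {}, {}, {}
    for ct in dict.fromkeys(groups.values()):
        cols = [s for s in state_df.columns if groups[s] == ct]
        support = min(ctx.config.min_support, len(cols))
        cons[ct] = consensus_state([state_df[c] for c in cols], support)
        bivalent = sorted(
            consensus_bivalent_genes([state_df[c] for c in cols], support)
        )
        (ctx.out / f"bivalent_genes_{ct}.txt").write_text(
            "".join(g + "\n" for g in bivalent)
        )
        bivalent_counts[ct] = len(bivalent)
        try:
            fractions[ct] = dynamics.bivalent_fraction_of_k27(cons[ct])
        except dynamics.UndefinedStatistic:
            fractions[ct] = None
    ctx.put("consensus_states", pd.DataFrame(cons))
    summary["state_counts"] = {
        s: {str(k): int(v) for k, v in col.value_counts(dropna=False).items()}
        for s, col in state_df.items()
    }
    summary["consensus_bivalent_counts"] = bivalent_counts
    summary["bivalent_fraction_of_k27"] = fractions


def _stage_prim(ctx: _Context, summary: dict) -> None:
    states = ctx.states_frame("states")
    k4 = ctx.frame("signals_k4")
    k27 = ctx.frame("signals_k27")
    groups = ctx.sample_groups()
    prim_samples = build_prim_table(states, k4, k27, ctx.config.pseudocount)
    ctx.put("prim_samples", prim_samples)
    prim_ct = build_prim_table(
        states, k4, k27, ctx.config.pseudocount,
        sample_groups=groups, min_support=ctx.config.min_support,
    )
    ctx.put("prim_celltypes", prim_ct)
    if prim_samples.shape[1] >= 3:
        pca = dynamics.pca_on_prim(prim_samples)
        ctx.put("pca", pca.coordinates)
        summary["pca_variance_fractions"] = [
            float(v) for v in pca.variance_fractions
        ]
    else:
        summary["pca_variance_fractions"] = None
    consensus = ctx.states_frame("consensus_states")
    cut_rows = []
    cutoffs = {}
    for ct in prim_ct.columns:
        cut = dynamics.derive_prim_cutoff(prim_ct[ct], consensus[ct])
        cutoffs[ct] = cut
        cut_rows.append(
            {"cell_type": ct, "threshold": cut.threshold, "quality": cut.quality}
        )
    ctx.put("cutoffs", pd.DataFrame(cut_rows).set_index("cell_type"))
    summary["prim_cutoffs"] = {
        ct: {"threshold": c.threshold, "quality": c.quality}
        for ct, c in cutoffs.items()
    }


def _stage_expression(ctx: _Context, summary: dict) -> bool:
    cfg = ctx.config
    if cfg.expression is None:
        summary["expression"] = {"skipped": "no expression table configured"}
        log.warning("expression stage skipped: no expression table")
        return False
    table = expr_mod.read_expression_tsv(cfg.expression, cfg.expression_groups)
    ctx.cache["expression_table"] = table
    de = expr_mod.select_differential_genes(table, cfg.fc_threshold, cfg.alpha)
    if len(de.genes) < 2:
        raise PipelineError("fewer than 2 differential genes; cannot cluster")
    clustering = expr_mod.hierarchical_cluster_genes(table.values.loc[de.genes])
    classes = expr_mod.assign_expression_classes(clustering, table)
    de_table = de.table.copy()
    de_table.insert(0, "class", classes)
    ctx.put("de_genes", de_table)
    summary["expression"] = {
        "n_selected": len(de.genes),
        "n_class_I": int((classes == "I").sum()),
        "n_class_II": int((classes == "II").sum()),
    }
    return True


def _stage_transitions(ctx: _Context, summary: dict) -> None:
    try:
        de_table = ctx.frame("de_genes")
    except PipelineError:
        summary["transitions"] = {"skipped": "expression stage did not run"}
        log.warning("transitions stage skipped: no differential genes")
        return
    classes = de_table["class"]
    consensus = ctx.states_frame("consensus_states")
    prim_ct = ctx.frame("prim_celltypes")
    cut_df = ctx.frame("cutoffs")
    cutoffs = {
        ct: dynamics.PrimCutoff(row["threshold"], row["quality"])
        for ct, row in cut_df.iterrows()
    }
    cats = dynamics.classify_transitions(classes, consensus, prim_ct, cutoffs)
    out = pd.DataFrame({"class": classes, "category": cats})
    ctx.put("transitions", out)
    for cat, grp in out.groupby("category"):
        (ctx.out / f"transitions_{cat}.txt").write_text(
            "".join(g + "\n" for g in sorted(grp.index))
        )
    summary["transitions"] = {
        str(k): int(v) for k, v in cats.value_counts().sort_index().items()
    }


def _stage_enhancers(ctx: _Context, summary: dict) -> None:
    cfg = ctx.config
    ac_rows = ctx.k27ac_rows()
    if ac_rows.empty:
        summary["enhancers"] = {"skipped": "no K27ac samples configured"}
        log.warning("enhancer stage skipped: no K27ac samples")
        return
    available = {
        ct for ct in dict.fromkeys(ctx.manifest["cell_type"])
        if ct in set(ac_rows["cell_type"])
    }
    cell_types = [ct for ct in enh.CELL_TYPES if ct in available] + sorted(
        available - set(enh.CELL_TYPES)
    )
    k27ac = {}
    for ct in cell_types:
        paths = ac_rows.loc[ac_rows["cell_type"] == ct, "peaks"]
        ivs = []
        for p in paths:
            ivs.extend(parse_bed(p, "K27ac", ct, ct).intervals)
        k27ac[ct] = PeakSet(f"{ct}_K27ac", ct, "K27ac", ivs)
    chip = ctx.chip_rows()
    k4me3 = {}
    for ct in cell_types:
        rows = chip[(chip["cell_type"] == ct) & (chip["mark"] == "K4me3")]
        if rows.empty:
            raise PipelineError(f"cell type {ct} has K27ac but no K4me3 peaks")
        ivs = []
        for p in rows["peaks"]:
            ivs.extend(parse_bed(p, "K4me3", ct, ct).intervals)
        k4me3[ct] = PeakSet(f"{ct}_K4me3", ct, "K4me3", ivs)
    catalog = enh.call_enhancers(
        k27ac, k4me3, ctx.annotation, ctx.layout,
        cfg.k4_extension, cfg.merge_gap, cell_types, cfg.k4_union,
    )
    catalog = enh.assign_activity(catalog, k27ac)
    catalog = enh.partition_activity(catalog)
    catalog = enh.annotate_enhancer_genes(
        catalog, ctx.annotation, cfg.annotation_window
    )
    table = catalog.table.copy()
    table["transcripts"] = table["transcripts"].map(
        lambda hits: ";".join(f"{t}:{g}:{d}" for t, g, d in hits)
    )
    ctx.put("enhancers", table.set_index("enhancer_id"))
    write_bed(
        catalog.intervals(),
        ctx.out / "enhancers.bed",
        names=list(catalog.table["enhancer_id"]),
        scores=[
            int(sum(r[f] for f in catalog.flag_columns()))
            for _, r in catalog.table.iterrows()
        ],
    )
    summary["enhancers"] = {
        "n_total": len(catalog),
        "subsets": {
            label: int((catalog.table["subset"] == label).sum())
            for label in enh.SUBSET_LABELS
        },
    }
    try:
        de_table = ctx.frame("de_genes")
    except PipelineError:
        summary["enhancer_class_association"] = {
            "skipped": "expression stage did not run"
        }
        return
    assoc = enh.class_association_summary(catalog, de_table["class"])
    ctx.put("enhancer_class_assoc", assoc)


def _stage_profiles(ctx: _Context, summary: dict) -> None:
    cfg = ctx.config
    promoters = ctx.promoters
    bivalent_path = ctx.out / "bivalent_genes_SSC.txt"
    if not bivalent_path.exists():
        raise PipelineError("bivalent_genes_SSC.txt missing; run the states stage")
    genes = [g for g in bivalent_path.read_text().split() if g]
    if len(genes) < max(cfg.k, 2):
        summary["profiles"] = {
            "skipped": f"only {len(genes)} SSC bivalent genes"
        }
        log.warning("profile stage skipped: too few bivalent genes")
        return
    sub = PromoterSet({g: promoters[g] for g in genes})
    chip = ctx.chip_rows()
    tracks = {}
    for row in chip.itertuples():
        tracks[(row.sample_id, row.mark)] = load_coverage(
            row.coverage, row.sample_id, row.mark, int(row.library_size)
        )
    pm = prof.tss_profile_matrix(tracks, sub, cfg.half_width, cfg.bin_width)
    for (sample, mark), block in pm.blocks.items():
        block.to_csv(ctx.out / f"profile_{sample}_{mark}.tsv", sep="\t")
    clusters = prof.kmeans_profile_clusters(pm, cfg.k, cfg.seed, cfg.restarts)
    ctx.put("profile_clusters", clusters.labels.to_frame())
    groups = {
        f"cluster{c}": list(clusters.labels.index[clusters.labels == c])
        for c in range(cfg.k)
    }
    first_ssc = sorted(k for k in pm.blocks if k[0].startswith("SSC"))
    if first_ssc:
        stats_df, pvals = prof.profile_group_stats(pm.blocks[first_ssc[0]], groups)
        ctx.put("profile_group_stats", stats_df)
        ctx.put("profile_group_pvals", pvals)
    summary["profiles"] = {
        "n_genes": len(genes),
        "k": cfg.k,
        "cluster_sizes": {str(c): n for c, n in sorted(clusters.sizes.items())},
        "degenerate": clusters.degenerate,
    }


_STAGE_FUNCS = {
    "promoters": _stage_promoters,
    "states": _stage_states,
    "prim": _stage_prim,
    "expression": _stage_expression,
    "transitions": _stage_transitions,
    "enhancers": _stage_enhancers,
    "profiles": _stage_profiles,
}


def run_pipeline(
    config: PipelineConfig, stages: Sequence[str] | None = None
) -> dict:
    """Execute the requested stages (all by default) and write summary.json."""
    requested = list(STAGES) if stages is None else list(stages)
    unknown = set(requested) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stages: {sorted(unknown)}")
    out = Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    ctx = _Context(config)
    summary_path = out / "summary.json"
    summary: dict = {}
    if stages is not None and summary_path.exists():
        summary = json.loads(summary_path.read_text())
    summary["parameters"] = {
        k: v for k, v in dataclasses.asdict(config).items() if k != "outdir"
    }
    summary["input_digests"] = {
        name: _digest(path)
        for name, path in (
            ("genome", config.genome),
            ("annotation", config.annotation),
            ("samples", config.samples),
            ("expression", config.expression),
        )
        if path is not None
    }
    log.info("run start: stages=%s", requested)
    for name in STAGES:
        if name not in requested:
            continue
        log.info("stage %s: start", name)
        try:
            _STAGE_FUNCS[name](ctx, summary)
        except PipelineError:
            raise
        except Exception as exc:  # noqa: BLE001 - re-raise with stage name
            summary["failed_stage"] = name
            summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True))
            raise PipelineError(f"stage {name} failed: {exc}") from exc
        log.info("stage %s: done", name)
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    log.info("run complete: %s", summary_path)
    return summary


def study_state_tables(
    study: SyntheticStudy,
) -> tuple[PromoterSet, pd.DataFrame, pd.DataFrame, pd.DataFrame, dict[str, str]]:
    """Promoters plus per-sample state/signal tables, computed in memory.

    Convenience for working on a SyntheticStudy without writing files:
    returns (promoters, states, k4_signals, k27_signals, sample_groups)
    exactly as the states stage would persist them.
    """
    promoters = define_promoters(
        study.annotation, study.config.promoter_flank, study.layout
    )
    states, k4, k27, groups = {}, {}, {}, {}
    for ct, reps in study.config.chip_replicates.items():
        for rep in range(1, reps + 1):
            sid = f"{ct}_rep{rep}"
            states[sid] = call_promoter_state(
                promoters,
                study.chip_peaks[(ct, rep, "K4me3")],
                study.chip_peaks[(ct, rep, "K27me3")],
            )
            k4[sid] = promoter_signal_column(
                study.coverage[(ct, rep, "K4me3")], promoters
            )
            k27[sid] = promoter_signal_column(
                study.coverage[(ct, rep, "K27me3")], promoters
            )
            groups[sid] = ct
    return (
        promoters,
        pd.DataFrame(states),
        pd.DataFrame(k4),
        pd.DataFrame(k27),
        groups,
    )


# ---------------------------------------------------------------------
# synthetic dataset emission
# ---------------------------------------------------------------------

def write_study(study: SyntheticStudy, outdir: str | Path) -> PipelineConfig:
    """Write a SyntheticStudy to disk in pipeline-readable formats.

    Emits genome.tsv, annotation.tsv, per-sample peak BEDs and coverage
    bedGraphs, per-cell-type K27ac BEDs, the expression TSV with its sample
    map, the ground-truth tables, a samples.tsv manifest and pipeline.yaml.
    Returns the ready PipelineConfig.
    """
    out = Path(outdir)
    for sub in ("peaks", "coverage", "truth", "results"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    study.layout.to_tsv(out / "genome.tsv")
    write_annotation(study.annotation, out / "annotation.tsv")
    manifest_rows = []
    for (ct, rep, mark), peaks in sorted(study.chip_peaks.items()):
        bed = out / "peaks" / f"{ct}_rep{rep}_{mark}.bed"
        write_bed(
            peaks.intervals,
            bed,
            names=[f"peak{i + 1}" for i in range(len(peaks))],
            scores=[iv.score or 0 for iv in peaks.intervals],
        )
        track = study.coverage[(ct, rep, mark)]
        bg = out / "coverage" / f"{ct}_rep{rep}_{mark}.bedGraph"
        write_bedgraph(track, bg)
        manifest_rows.append(
            {
                "sample_id": f"{ct}_rep{rep}",
                "cell_type": ct,
                "replicate": rep,
                "mark": mark,
                "peaks": str(bed),
                "coverage": str(bg),
                "library_size": track.library_size,
            }
        )
    for ct, peaks in sorted(study.k27ac_peaks.items()):
        bed = out / "peaks" / f"{ct}_K27ac.bed"
        write_bed(
            peaks.intervals,
            bed,
            names=[f"peak{i + 1}" for i in range(len(peaks))],
            scores=[iv.score or 0 for iv in peaks.intervals],
        )
        manifest_rows.append(
            {
                "sample_id": f"{ct}_K27ac",
                "cell_type": ct,
                "replicate": 0,
                "mark": "K27ac",
                "peaks": str(bed),
                "coverage": "",
                "library_size": 0,
            }
        )
    manifest = pd.DataFrame(manifest_rows)
    manifest.to_csv(out / "samples.tsv", sep="\t", index=False)
    study.expression.values.rename_axis("gene").to_csv(
        out / "expression.tsv", sep="\t"
    )
    pd.DataFrame(
        {
            "sample": list(study.expression.sample_groups),
            "cell_type": list(study.expression.sample_groups.values()),
        }
    ).to_csv(out / "expression_groups.tsv", sep="\t", index=False)
    truth = study.truth
    truth.states.to_csv(out / "truth" / "states.tsv", sep="\t")
    pd.DataFrame(
        {"class": truth.expression_class, "category": truth.transition_category}
    ).to_csv(out / "truth" / "classes.tsv", sep="\t")
    if truth.enhancers is not None:
        truth.enhancers.to_csv(out / "truth" / "enhancers.tsv", sep="\t", index=False)
    config = PipelineConfig(
        genome=str(out / "genome.tsv"),
        annotation=str(out / "annotation.tsv"),
        samples=str(out / "samples.tsv"),
        expression=str(out / "expression.tsv"),
        expression_groups=str(out / "expression_groups.tsv"),
        outdir=str(out / "results"),
        flank=study.config.promoter_flank,
        seed=study.config.seed,
    )
    config.to_yaml(out / "pipeline.yaml")
    return config
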