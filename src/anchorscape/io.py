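"""Readers, writers and the end-to-end pipeline driver.

Tab-delimited text throughout: anchor tables (`id, variant, fitness, route,
passage, source`), epistasis reports, graph edge lists and design rankings.
Reference sequences are single-record FASTA.  :func:`run_pipeline` chains
the stages (ingest/simulate → summarize → epistasis → graph → train →
design → compress) and writes a JSON manifest recording seeds and input
checksums so a run is reproducible end to end.
"""

from __future__ import annotations

import hashlib
import json
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from . import design as design_mod
from . import epistasis as epi_mod
from . import model as model_mod
from . import relation_map as graph_mod
from . import simulate as sim_mod
from .variants import AnchorRecord, AnchorSet, parse_variant, summarize_anchors

ANCHOR_COLUMNS = ("id", "variant", "fitness", "route", "passage", "source")


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name for error routing."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def read_reference_fasta(path: str | Path) -> tuple[str, str]:
    """(sequence, id) from a single-record FASTA."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise ValueError(f"{path}: expected exactly one FASTA record, got {len(records)}")
    return str(records[0].seq), records[0].id


def write_reference_fasta(path: str | Path, sequence: str, ref_id: str = "ref") -> None:
    SeqIO.write([SeqRecord(Seq(sequence), id=ref_id, description="")], str(path), "fasta")


def write_anchor_table(s: AnchorSet, path: str | Path) -> None:
    rows = [
        {"id": rec.record_id, "variant": rec.variant.label(),
         "fitness": repr(rec.fitness), "route": rec.route_id,
         "passage": rec.passage, "source": rec.source}
        for rec in s
    ]
    pd.DataFrame(rows, columns=list(ANCHOR_COLUMNS)).to_csv(
        path, sep="\t", index=False)


def read_anchor_table(path: str | Path, reference: str,
                      reference_id: str = "ref") -> AnchorSet:
    """Validated AnchorSet from a TSV; errors name the offending row."""
    df = pd.read_csv(path, sep="\t", dtype={"variant": str, "route": str})
    missing = [c for c in ANCHOR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    records = []
    for pos, row in enumerate(df.itertuples(index=False), start=2):  # header is line 1
        try:
            variant = parse_variant(str(row.variant), reference, reference_id)
            fitness = float(row.fitness)
            if not fitness > 0:
                raise ValueError(f"fitness must be > 0, got {fitness}")
            records.append(AnchorRecord(
                variant=variant, fitness=fitness,
                route_id="" if pd.isna(row.route) else str(row.route),
                passage=int(row.passage), source=str(row.source),
                record_id=str(row.id)))
        except (ValueError, TypeError) as err:
            raise ValueError(f"{path} row {pos}: {err}") from None
    return AnchorSet(reference, records, reference_id)


def write_epistasis_table(report: epi_mod.ScanReport, path: str | Path) -> None:
    rows = []
    for r in report.results:
        q = r.query
        rows.append({
            "background": q.background.label() if q else "",
            "group_a": "+".join(sorted(str(m) for m in q.group_a)) if q else "",
            "group_b": "+".join(sorted(str(m) for m in q.group_b)) if q else "",
            "epsilon": r.epsilon, "class": r.klass,
            "effect_a_in_bg": r.effect_a_in_bg,
            "effect_a_with_b": r.effect_a_with_b,
            "effect_b_in_bg": r.effect_b_in_bg,
            "effect_b_with_a": r.effect_b_with_a,
        })
    pd.DataFrame(rows, columns=["background", "group_a", "group_b", "epsilon",
                                "class", "effect_a_in_bg", "effect_a_with_b",
                                "effect_b_in_bg", "effect_b_with_a"]
                 ).to_csv(path, sep="\t", index=False)


def write_edge_list(g, path: str | Path) -> None:
    rows = [{"variant_a": a, "variant_b": b, "distance": d["distance"]}
            for a, b, d in sorted(g.edges(data=True))]
    pd.DataFrame(rows, columns=["variant_a", "variant_b", "distance"]).to_csv(
        path, sep="\t", index=False)


def write_graphml(g, path: str | Path) -> None:
    import networkx as nx

    h = g.copy()
    for _, data in h.nodes(data=True):
        data.pop("variant", None)  # GraphML carries scalars only
    nx.write_graphml(h, str(path))


def write_design_table(ranked: Sequence[tuple], path: str | Path) -> None:
    rows = [{"rank": i + 1, "variant": v.label(), "predicted_score": s}
            for i, (v, s) in enumerate(ranked)]
    pd.DataFrame(rows, columns=["rank", "variant", "predicted_score"]).to_csv(
        path, sep="\t", index=False)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


@dataclass
class PipelineConfig:
    """Everything one end-to-end run needs; the seed drives every stage."""

    out_dir: str
    anchor_table: str | None = None       # ingest an existing table ...
    reference_fasta: str | None = None
    use_fixture: bool = True              # ... or fall back to the benchmark set
    seed: int = 0
    max_distance: int = 2
    epistasis_tolerance: float = 0.0
    max_group_size: int = 2
    feature_mode: str = "onehot"
    model: model_mod.ModelConfig = field(default_factory=model_mod.ModelConfig)
    split_sizes: tuple[int, int, int] = (59, 7, 16)
    design_k: int = 3
    design_top_n: int = 10
    alphabet: int = 20
    log_level: str = "info"


def _log(cfg: PipelineConfig, stage: str, msg: str) -> None:
    if cfg.log_level != "quiet":
        print(f"[{stage}] {msg}", file=sys.stderr)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run ingest → summarize → epistasis → graph → train → design → compress.

    Returns the manifest dict (also written to ``manifest.json``).  Any
    stage failure raises :class:`StageError` naming the stage.
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": cfg.seed, "stages": {}, "inputs": {}, "outputs": {}}

    stage = "ingest"
    try:
        if cfg.anchor_table is not None:
            if cfg.reference_fasta is None:
                raise ValueError("anchor_table requires reference_fasta")
            reference, ref_id = read_reference_fasta(cfg.reference_fasta)
            anchors = read_anchor_table(cfg.anchor_table, reference, ref_id)
            manifest["inputs"]["anchor_table"] = _sha256(Path(cfg.anchor_table))
            manifest["inputs"]["reference_fasta"] = _sha256(Path(cfg.reference_fasta))
        elif cfg.use_fixture:
            anchors = sim_mod.make_anchor_fixture()
            manifest["inputs"]["anchor_table"] = "fixture"
        else:
            raise ValueError("no anchor source configured")
        write_anchor_table(anchors, out / "anchors.tsv")
        write_reference_fasta(out / "reference.fasta", anchors.reference_sequence,
                              anchors.reference_id)
        _log(cfg, stage, f"{len(anchors)} anchor records")
    except StageError:
        raise
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "summarize"
    try:
        summary = summarize_anchors(anchors)
        manifest["stages"]["summary"] = {
            "n_variants": summary.n_variants,
            "n_distinct_mutations": summary.n_distinct_mutations,
            "n_distinct_sites": summary.n_distinct_sites,
            "fraction_gt2_mutations": summary.fraction_gt2_mutations,
        }
        _log(cfg, stage, f"{summary.n_variants} variants, "
                         f"{summary.n_distinct_mutations} mutations, "
                         f"{summary.n_distinct_sites} sites")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "epistasis"
    try:
        queries = epi_mod.enumerate_quadruples(anchors, cfg.max_group_size)
        report = epi_mod.scan_epistasis(anchors, queries, cfg.epistasis_tolerance)
        write_epistasis_table(report, out / "epistasis.tsv")
        manifest["stages"]["epistasis"] = {
            "n_queries": len(queries), "n_results": len(report.results)}
        _log(cfg, stage, f"{len(report.results)} quadruples evaluated")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "graph"
    try:
        g = graph_mod.build_relation_graph(anchors, cfg.max_distance)
        write_edge_list(g, out / "edges.tsv")
        write_graphml(g, out / "graph.graphml")
        manifest["stages"]["graph"] = {
            "n_nodes": g.number_of_nodes(), "n_edges": g.number_of_edges()}
        _log(cfg, stage, f"{g.number_of_nodes()} nodes, {g.number_of_edges()} edges")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "train"
    try:
        vocab = tuple(sorted({m for rec in anchors for m in rec.variant.mutations},
                             key=lambda m: (m.site, m.mut_aa)))
        spec = model_mod.FeatureSpec(cfg.feature_mode, vocab)
        ids = [rec.record_id for rec in anchors]
        sizes = cfg.split_sizes
        if sum(sizes) != len(ids):  # rescale the default split to the data
            n = len(ids)
            n_tr = max(2, round(n * sizes[0] / sum(sizes)))
            n_va = max(0, round(n * sizes[1] / sum(sizes)))
            sizes = (n_tr, n_va, n - n_tr - n_va)
        split = model_mod.SplitPlan.random(ids, cfg.seed, sizes)
        cfg_model = model_mod.ModelConfig(
            **{**cfg.model.__dict__, "seed": cfg.seed})
        fitted = model_mod.train_model(anchors, spec, cfg_model, split)
        rho_test = model_mod.evaluate_split(fitted, anchors, split.test_ids) \
            if len(split.test_ids) >= 2 else float("nan")
        pd.DataFrame(fitted.loss_curve,
                     columns=["epoch", "train_loss", "val_loss"]).to_csv(
            out / "training_log.tsv", sep="\t", index=False)
        manifest["stages"]["train"] = {
            "feature_mode": cfg.feature_mode,
            "weight_checksum": fitted.weight_checksum(),
            "test_spearman_rho": rho_test,
        }
        _log(cfg, stage, f"test Spearman rho = {rho_test:.3f}")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "design"
    try:
        dspec = design_mod.DesignSpec(candidates=vocab, k=cfg.design_k,
                                      include_wildtype=True,
                                      reference_id=anchors.reference_id)
        designs = design_mod.enumerate_designs(dspec)
        ranked = design_mod.rank_designs(fitted, designs, cfg.design_top_n)
        write_design_table(ranked, out / "designs.tsv")
        manifest["stages"]["design"] = {
            "k": cfg.design_k, "n_designs": len(designs),
            "top_design": ranked[0][0].label() if ranked else ""}
        _log(cfg, stage, f"{len(designs)} designs enumerated")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    stage = "compress"
    try:
        rep = design_mod.compression_report(
            summary.n_distinct_sites, cfg.alphabet, summary.n_variants)
        manifest["stages"]["compress"] = {
            "space_size_log10": rep.space_size_log10,
            "ratio_log10": rep.ratio_log10,
            "space_exponent": rep.space_exponent,
            "ratio_exponent": rep.ratio_exponent,
        }
        _log(cfg, stage, f"space ~10^{rep.space_exponent}, "
                         f"ratio ~10^{rep.ratio_exponent}")
    except Exception as err:
        raise StageError(stage, str(err)) from err

    for f in sorted(out.iterdir()):
        if f.name != "manifest.json" and f.is_file():
            manifest["outputs"][f.name] = _sha256(f)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
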