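"""End-to-end pipeline with a run manifest and resumable stages.

``run_pipeline`` executes the full workflow — filter, bin, balance,
expected model, detect, refine, graph, permutation test, report — into a
run directory, recording every stage, its parameters and outputs in
``manifest.json``. Re-running with ``resume=True`` skips stages whose
outputs already exist, regenerating only what is missing downstream.
All randomness flows from the single config seed.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__ as _pkg_version
from . import contacts, detection, normalization, permutation, plotting, refinement
from .genome import (
    FragmentMap,
    digest_fasta,
    fragment_map_from_bed,
    read_bed,
    subtract_gaps,
)
from .model import TranslocationModel
from .rearrangements import (
    annotate_deletion_bridges,
    chains_to_json,
    junctions_to_links,
    read_copy_number_segments,
)

log = logging.getLogger("hicplexy")

EXIT_BAD_INPUT = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    pairs: str
    out_dir: str
    fasta: str | None = None
    fragments_bed: str | None = None
    genes_bed: str | None = None
    gaps_bed: str | None = None
    segments_tsv: str | None = None
    bin_size: int = 100_000
    display_bin_size: int = 2_500_000
    fdr: float = 0.001
    min_intra_distance: int = 25_000_000
    window_half_width: int = 1_000_000
    min_mapq: int | None = None
    # distance-to-cut-site filter: enable (e.g. 1000) for real libraries,
    # whose reads anchor at restriction sites; synthetic reads are placed
    # uniformly within fragments and would be decimated by it
    max_frag_distance: int | None = None
    link_distance: int = 2_000_000
    perm_k: int | None = None  # default: number of unique fragments observed
    perm_m: int = 100_000
    seed: int = 0
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)


def _stage(manifest: dict, name: str, outputs: list[Path], resume: bool):
    """Decide whether a stage can be skipped under --resume."""
    done = (
        resume
        and name in manifest["stages"]
        and manifest["stages"][name]["status"] == "completed"
        and all(p.exists() for p in outputs)
    )
    return done


def run_pipeline(config: PipelineConfig, resume: bool = False) -> dict:
    """Execute all stages; returns the manifest dictionary."""
    logging.basicConfig(
        stream=sys.stderr,
        level=getattr(logging, config.log_level.upper(), logging.INFO),
        format="[%(name)s:%(stage)s] %(message)s",
    )
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest_path = out / "manifest.json"
    manifest: dict = {"version": _pkg_version, "config": asdict(config), "stages": {}}
    if resume and manifest_path.exists():
        manifest = json.loads(manifest_path.read_text())
        manifest["config"] = asdict(config)

    def _log(stage: str, msg: str) -> None:
        log.info(msg, extra={"stage": stage})

    def _record(stage: str, outputs: list[Path], t0: float) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "outputs": [str(p) for p in outputs],
            "seconds": round(time.time() - t0, 3),
        }
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")

    def _run(stage: str, outputs: list[Path], fn) -> bool:
        """Run ``fn`` unless resume lets us skip; returns True if executed."""
        if _stage(manifest, stage, outputs, resume):
            _log(stage, "skipped (resume: outputs present)")
            return False
        t0 = time.time()
        try:
            fn()
        except Exception as exc:  # pragma: no cover - error path
            manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
            manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
            raise StageError(stage, str(exc)) from exc
        _record(stage, outputs, t0)
        return True

    # ---- load inputs -----------------------------------------------------
    if config.fragments_bed:
        fragments = fragment_map_from_bed(config.fragments_bed)
    elif config.fasta:
        fragments = digest_fasta(config.fasta)
    else:
        raise StageError("input", "need fragments_bed or fasta")
    if config.gaps_bed:
        fragments = subtract_gaps(fragments, read_bed(config.gaps_bed))
    genes = read_bed(config.genes_bed) if config.genes_bed else []

    model = TranslocationModel(
        contacts.read_pairs(config.pairs, fragments.genome),
        fragments,
        bin_size=config.bin_size,
        detection_params=detection.DetectionParams(
            fdr=config.fdr, min_intra_distance=config.min_intra_distance
        ),
        refinement_params=refinement.RefinementParams(
            window_half_width=config.window_half_width
        ),
        min_mapq=config.min_mapq,
        max_frag_distance=config.max_frag_distance,
    )

    state: dict = {}

    # The fit is a single in-memory chain; file outputs are written per
    # stage so --resume can skip the cheap re-exports of completed stages.
    def fit() -> None:
        state["results"] = model.fit()

    # the fit itself always runs (it is the in-memory state every export
    # stage reads from); only the file exports participate in --resume
    t0 = time.time()
    try:
        fit()
    except Exception as exc:
        manifest["stages"]["fit"] = {"status": "failed", "error": str(exc)}
        manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
        raise StageError("fit", str(exc)) from exc
    _record("fit", [], t0)
    res = state["results"]

    def export_filter() -> None:
        (out / "filter_report.json").write_text(
            json.dumps(res.filter_report.as_dict(), indent=2) + "\n"
        )

    def export_matrix() -> None:
        res.matrix.to_triples(out / "matrix.triples.tsv")
        res.matrix.bins_to_bed(out / "bins.bed")

    def export_normalization() -> None:
        with open(out / "factors.tsv", "w") as fh:
            fh.write("#bin\tfactor\tincluded\n")
            for i, (f, inc) in enumerate(
                zip(res.balance.factors, res.balance.included)
            ):
                fh.write(f"{i}\t{f:.6g}\t{int(inc)}\n")
        with open(out / "decay.tsv", "w") as fh:
            fh.write("#stratum\tmean_balanced_count\n")
            for s, v in res.expected.decay_table():
                fh.write(f"{int(s)}\t{v:.6g}\n")

    def export_detection() -> None:
        res.calls.table.to_csv(out / "calls.tsv", sep="\t", index=False)
        res.to_bedpe(out / "candidates.bedpe")

    def export_refinement() -> None:
        for pair in res.breakpoints:
            for side in pair:
                refinement.annotate_genes(side, genes)
        res.breakpoint_table().to_csv(out / "breakpoints.tsv", sep="\t", index=False)

    def export_graph() -> None:
        segments = (
            read_copy_number_segments(config.segments_tsv)
            if config.segments_tsv
            else None
        )
        graph = res.build_rearrangement_graph(config.link_distance, segments)
        chains_to_json(res.chains, out / "chains.json")
        junctions_to_links(graph, out / "links.txt")

    def run_permtest() -> None:
        cfg = permutation.PermutationConfig(
            k=config.perm_k or max(
                len({(s.interval.chrom, s.interval.start, s.interval.end)
                     for p in res.breakpoints for s in p
                     if s.resolution == "fragment"}), 1),
            m=config.perm_m,
            seed=config.seed,
        )
        result = res.test_gene_enrichment(genes, cfg)
        result.to_json(out / "permutation.json")

    def export_report() -> None:
        (out / "summary.txt").write_text(res.summary() + "\n")
        plotting.export_heatmap(
            res.ratio,
            display_bin_size=config.display_bin_size,
            txt_path=out / "heatmap.tsv",
            png_path=out / "heatmap.png",
        )

    _run("filter", [out / "filter_report.json"], export_filter)
    _run("bin", [out / "matrix.triples.tsv", out / "bins.bed"], export_matrix)
    _run("normalize", [out / "factors.tsv", out / "decay.tsv"], export_normalization)
    _run("detect", [out / "calls.tsv", out / "candidates.bedpe"], export_detection)
    _run("refine", [out / "breakpoints.tsv"], export_refinement)
    _run("graph", [out / "chains.json", out / "links.txt"], export_graph)
    if genes and res.breakpoints:
        _run("permtest", [out / "permutation.json"], run_permtest)
    else:
        manifest["stages"].setdefault(
            "permtest", {"status": "skipped", "reason": "no genes or breakpoints"}
        )
    _run("report", [out / "summary.txt", out / "heatmap.tsv"], export_report)

    manifest_path.write_text(json.dumps(manifest, indent=2) + "\n")
    return manifest
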