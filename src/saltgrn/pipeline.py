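"""End-to-end driver: candidate funnel -> per-condition consensus ->
evidence-integrated report, with every intermediate written to disk and a
manifest recording versions, seeds and parameters.

A run is fully determined by its :class:`PipelineConfig`: rerunning with
the same config reproduces every artifact byte-for-byte (the manifest's
timestamp aside).
"""

from __future__ import annotations

import dataclasses
import datetime
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import __version__, io
from .consensus import run_consensus
from .engine import InferenceParams
from .evidence import build_report
from .funnel import build_candidate_list, call_degs, moderated_t_test, overlap_sets

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """Stage-labeled pipeline failure."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Flat configuration of one pipeline run.

    Input paths: the expression matrix and its sample metadata are
    required; ``y1h_hits``, ``known_regulators``, ``binding`` and
    ``candidates`` (an explicit pre-built panel, which bypasses the
    funnel) are optional gene-list files.  ``overlap_deg_list`` is an
    optional second DEG set (e.g. from an independent developmental
    dataset) intersected with the DEGs called here before the funnel.
    """

    expression: str
    sample_metadata: str
    target: str
    y1h_hits: str | None = None
    known_regulators: str | None = None
    binding: str | None = None
    candidates: str | None = None
    overlap_deg_list: str | None = None
    stress_condition: str = "stress"
    control_condition: str = "control"
    lfc_min: float = 1.0
    p_max: float = 0.001
    use_adjusted: bool = True
    direction: str = "both"
    n_runs: int = 100
    base_seed: int = 0
    min_freq_stress: float = 0.80
    min_freq_control: float = 0.40
    extraction: str = "positive"
    k: int | None = None
    inference: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def params(self) -> InferenceParams:
        return InferenceParams(**self.inference)


def _stage(name: str):
    def wrap(fn):
        def run(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(name, str(exc)) from exc

        return run

    return wrap


def run_pipeline(config: PipelineConfig, out_dir) -> "pd.DataFrame":
    """Execute funnel -> per-condition consensus -> integration.

    Writes ``deg_table.tsv``, ``candidates.tsv``, ``consensus_stress.tsv``,
    ``consensus_control.tsv``, ``report.tsv``/``report.json`` and
    ``manifest.json`` under ``out_dir`` and returns the report DataFrame.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "saltgrn_version": __version__,
        "timestamp": datetime.datetime.now(datetime.timezone.utc).isoformat(),
        "config": config.to_dict(),
        "stages": {},
        "artifacts": {},
        "status": "running",
    }

    @_stage("load")
    def load():
        for name in ("expression", "sample_metadata"):
            p = getattr(config, name)
            if p is None or not Path(p).exists():
                raise FileNotFoundError(f"missing input: {name}={p}")
        em = io.read_expression(config.expression, config.sample_metadata)
        manifest["stages"]["load"] = {"genes": len(em.genes), "samples": em.values.shape[1]}
        return em

    @_stage("deg")
    def deg(em):
        stress = em.condition_samples(config.stress_condition)
        control = em.condition_samples(config.control_condition)
        table = moderated_t_test(em.values, stress, control)
        io.write_deg_table(table, out / "deg_table.tsv")
        degs = call_degs(table, config.lfc_min, config.p_max, config.use_adjusted, config.direction)
        manifest["stages"]["deg"] = {
            "n_stress_samples": len(stress),
            "n_control_samples": len(control),
            "n_degs": len(degs),
        }
        return degs

    @_stage("funnel")
    def funnel(em, degs):
        if config.candidates is not None:
            cand = io.read_candidates(config.candidates)
            manifest["stages"]["funnel"] = {"mode": "explicit", "n_candidates": len(cand)}
        else:
            overlap = degs
            if config.overlap_deg_list is not None:
                other = set(io.read_gene_list(config.overlap_deg_list))
                overlap = overlap_sets(degs, other).intersection
            y1h = set(io.read_gene_list(config.y1h_hits)) if config.y1h_hits else set()
            known = set(io.read_gene_list(config.known_regulators)) if config.known_regulators else set()
            cand = build_candidate_list(overlap, y1h, known, config.target)
            manifest["stages"]["funnel"] = {
                "mode": "funnel",
                "n_degs": len(degs),
                "n_overlap": len(overlap),
                "n_y1h": len(y1h),
                "n_known": len(known),
                "n_candidates": len(cand),
            }
        missing = set(cand.genes) - set(em.genes)
        if missing:
            raise ValueError(f"candidates absent from matrix: {sorted(missing)}")
        io.write_candidates(cand, out / "candidates.tsv")
        return cand

    @_stage("consensus")
    def consensus(em, cand, condition, base_seed, label):
        samples = em.condition_samples(condition)
        if not samples:
            raise ValueError(f"no samples for condition {condition!r}")
        sub = em.subset_samples(samples)
        table = run_consensus(
            sub,
            cand.genes,
            config.target,
            n_runs=config.n_runs,
            base_seed=base_seed,
            params=config.params(),
            extraction=config.extraction,
            k=config.k,
        )
        io.write_consensus(table, out / f"consensus_{label}.tsv")
        manifest["stages"][f"consensus_{label}"] = {
            "condition": condition,
            "n_samples": len(samples),
            "n_runs": config.n_runs,
            "base_seed": base_seed,
            "n_predicted": int((table["count"] > 0).sum()),
        }
        return table

    @_stage("report")
    def report(stress_table, control_table):
        binding = set(io.read_gene_list(config.binding)) if config.binding else set()
        rep = build_report(
            stress_table,
            control_table,
            thresholds=(config.min_freq_stress, config.min_freq_control),
            binding_set=binding,
        )
        io.write_report(rep, out / "report.tsv", out / "report.json")
        manifest["stages"]["report"] = {
            "n_binding": len(binding),
            "n_reported": len(rep),
            "classes": rep["class"].value_counts().to_dict() if not rep.empty else {},
        }
        return rep

    try:
        em = load()
        degs = deg(em)
        cand = funnel(em, degs)
        stress_table = consensus(em, cand, config.stress_condition, config.base_seed, "stress")
        control_table = consensus(
            em, cand, config.control_condition, config.base_seed + config.n_runs, "control"
        )
        rep = report(stress_table, control_table)
        manifest["status"] = "complete"
    except PipelineError as exc:
        manifest["status"] = f"failed:{exc.stage}"
        io.write_manifest(manifest, out / "manifest.json")
        raise
    for name in (
        "deg_table.tsv",
        "candidates.tsv",
        "consensus_stress.tsv",
        "consensus_control.tsv",
        "report.tsv",
        "report.json",
    ):
        manifest["artifacts"][name] = io.sha256_of(out / name)
    io.write_manifest(manifest, out / "manifest.json")
    return rep
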