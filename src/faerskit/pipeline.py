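"""End-to-end orchestration: ingest -> dedup -> stats -> signals -> summaries.

``run_pipeline`` executes the full analysis for one target drug over
either real quarterly ASCII tables or a synthetic universe, writing a
flow report (counts at each filter step), the statistics tables, the
ranked signal tables, demographic/onset/mortality summaries, and a
machine-readable run manifest.  Outputs are deterministic for a fixed
seed; a failed stage leaves partial outputs alongside a FAILED marker.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import __version__
from .io import MeddraMap, RawRecordSet, read_quarter
from .preprocess import (
    MatchLevel,
    assemble_cases,
    compute_onsets,
    deduplicate,
    match_target_drug,
)
from .reporting import demographic_summary, mortality_comparison, onset_summary
from .signals import (
    SubgroupSpec,
    compute_signal_table,
    rank_by_frequency,
    rank_by_intensity,
    signal_table_to_frame,
    subgroup_analysis,
)
from .synthetic import DEFAULT_TARGET_NAMES, SyntheticConfig, generate

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    out_dir: str = "faerskit_out"
    target_names: list[str] = field(
        default_factory=lambda: list(DEFAULT_TARGET_NAMES))
    input_paths: dict[str, str] | None = None  # table kind -> path
    meddra_path: str | None = None
    synthetic: SyntheticConfig | None = None
    stratify: list[str] = field(default_factory=list)
    criteria: str = "all4"
    top_k: int = 30
    ic_variant: str = "shrunk"
    yates: bool = True
    use_chi2_with_prr: bool = True
    seed: int = 0


def _jsonable(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, frozenset)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, float) and (obj != obj):  # NaN -> null
        return None
    return obj


def _write_json(path: Path, obj: Any) -> None:
    path.write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True,
                               default=str) + "\n", encoding="utf-8")


def _config_hash(config: PipelineConfig) -> str:
    payload = json.dumps(_jsonable(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Run the full analysis; returns the flow report and artifact paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    try:
        return _run(config, out)
    except Exception as exc:
        failed_marker.write_text(f"{type(exc).__name__}: {exc}\n")
        raise PipelineError(str(exc)) from exc


def _run(config: PipelineConfig, out: Path) -> dict[str, Any]:
    flow: dict[str, int] = {}
    artifacts: dict[str, str] = {}

    if config.synthetic is not None:
        syn = dataclasses.replace(config.synthetic, seed=config.seed)
        records, _truth = generate(syn)
        target_names = config.target_names or syn.target_drug_names
        meddra = syn.meddra_map()
    elif config.input_paths:
        records = read_quarter(config.input_paths)
        target_names = config.target_names
        meddra = (MeddraMap.read(config.meddra_path)
                  if config.meddra_path else None)
    else:
        raise PipelineError("config names neither input tables nor a "
                            "synthetic universe")

    flow["raw_demo_rows"] = len(records.demo)
    flow["rejected_rows"] = len(records.rejects)

    deduped = deduplicate(records)
    flow["deduplicated_reports"] = len(deduped.demo)

    cases, stats = assemble_cases(deduped)
    flow["cases_with_reactions"] = len(cases)
    flow["dropped_no_reactions"] = stats.n_no_reactions

    levels = [match_target_drug(c, target_names) for c in cases]
    flow["target_any_role"] = sum(l is not MatchLevel.NONE for l in levels)
    flow["target_primary_suspect"] = sum(
        l is MatchLevel.PRIMARY_SUSPECT for l in levels)

    ps_cases = [c for c, l in zip(cases, levels)
                if l is MatchLevel.PRIMARY_SUSPECT]
    onsets, onset_rejections = compute_onsets(ps_cases, target_names)
    flow["onset_computable"] = len(onsets)

    results, fit = compute_signal_table(
        cases, target_names, meddra=meddra,
        ic_variant=config.ic_variant, yates=config.yates,
        use_chi2_with_prr=config.use_chi2_with_prr)
    frame = signal_table_to_frame(results)
    stats_path = out / "signal_table.tsv"
    frame.to_csv(stats_path, sep="\t", index=False, float_format="%.6g")
    artifacts["signal_table"] = str(stats_path)

    for name, ranker in (("top_frequency", rank_by_frequency),
                         ("top_intensity", rank_by_intensity)):
        ranked = ranker(results, config.top_k, criteria=config.criteria)
        path = out / f"{name}.tsv"
        signal_table_to_frame(ranked).to_csv(path, sep="\t", index=False,
                                             float_format="%.6g")
        artifacts[name] = str(path)

    for variable in config.stratify:
        spec = SubgroupSpec(variable=variable)
        per_level = subgroup_analysis(cases, target_names, spec, meddra=meddra)
        for level, res in per_level.items():
            path = out / f"signals_{variable}_{level}.tsv"
            signal_table_to_frame(res).to_csv(path, sep="\t", index=False,
                                              float_format="%.6g")
            artifacts[f"signals_{variable}_{level}"] = str(path)

    demo = demographic_summary(ps_cases, onsets=onsets)
    _write_json(out / "demographics.json", demo)
    artifacts["demographics"] = str(out / "demographics.json")

    _write_json(out / "onset.json", onset_summary(onsets))
    artifacts["onset"] = str(out / "onset.json")

    _write_json(out / "mortality.json", mortality_comparison(ps_cases))
    artifacts["mortality"] = str(out / "mortality.json")

    flow_report = {
        "flow": flow,
        "onset_rejections": {r.name: v for r, v in onset_rejections.items()},
        "gps_prior_fallback": bool(fit.fallback) if fit else None,
    }
    _write_json(out / "flow.json", flow_report)
    artifacts["flow"] = str(out / "flow.json")

    manifest = {
        "seed": config.seed,
        "config_hash": _config_hash(config),
        "faerskit_version": __version__,
        "n_signal_rows": len(results),
    }
    _write_json(out / "manifest.json", manifest)
    artifacts["manifest"] = str(out / "manifest.json")
    return {"flow": flow_report, "artifacts": artifacts}
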