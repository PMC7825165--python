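"""Pipeline orchestration: config, stage execution, manifest, reports.

A single YAML config drives the whole chain
(simulate → call → filter → merge → classify → summarize → compare → vst →
report).  Every analysis constant sits under a named key with the standard
default (100 bp windows; p < 0.01, > 1 kb, q0 < 0.5 call filters; 0.4/1.6
copy-number class bounds; top-5 % VST cut).  Unknown keys are rejected
fail-fast, and a run manifest records the seed, parameters and per-stage
record counts.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import yaml

from cnvpop import caller as _caller
from cnvpop import cnvr as _cnvr
from cnvpop import overlap as _overlap
from cnvpop import report as _report
from cnvpop import synthetic as _syn
from cnvpop import vst as _vst
from cnvpop.qpcr import build_measurements, concordance, copy_number_from_ddct, read_ct_table

__all__ = ["PipelineConfig", "PipelineError", "run_pipeline", "render_reports"]

log = logging.getLogger("cnvpop")

_CALLER_DEFAULTS = {
    "pval": 0.01,
    "min_size": 1000,
    "max_q0": 0.5,
    "call_threshold": 0.5,
    "trimmed_mean": True,
    "t": 3.5,
    "merge_eps": 0.3,
    "bandwidths": [2, 4, 8, 16],
}
_CLASSIFY_DEFAULTS = {"deleted_below": 0.4, "duplicated_above": 1.6}
_VST_DEFAULTS = {"enabled": True, "mode": "top_fraction", "cutoff": 0.05}


def _merge_section(name: str, defaults: dict, given: dict | None) -> dict:
    out = dict(defaults)
    if given:
        unknown = set(given) - set(defaults)
        if unknown:
            raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
        out.update(given)
    return out


@dataclass
class PipelineConfig:
    """Validated pipeline configuration; round-trips losslessly via YAML."""

    seed: int
    output_dir: str
    window_size: int = 100
    simulate: dict | None = None
    inputs: dict | None = None  # depth_dir, groups_table
    caller: dict = field(default_factory=dict)
    classify: dict = field(default_factory=dict)
    vst: dict = field(default_factory=dict)
    compare: dict | None = None  # references: [...], qtl: {...}, genes: {...}

    def __post_init__(self) -> None:
        self.caller = _merge_section("caller", _CALLER_DEFAULTS, self.caller)
        self.classify = _merge_section("classify", _CLASSIFY_DEFAULTS, self.classify)
        self.vst = _merge_section("vst", _VST_DEFAULTS, self.vst)
        if self.inputs is not None:
            unknown = set(self.inputs) - {"depth_dir", "groups_table"}
            if unknown:
                raise ValueError(f"unknown keys in config section 'inputs': {sorted(unknown)}")
        if self.compare is not None:
            unknown = set(self.compare) - {"references", "qtl", "genes"}
            if unknown:
                raise ValueError(f"unknown keys in config section 'compare': {sorted(unknown)}")
        if self.simulate is None and self.inputs is None:
            raise ValueError("config needs either a 'simulate' section or 'inputs'")
        if not 0 <= self.caller["pval"] <= 1:
            raise ValueError("caller.pval must be in [0, 1]")
        if not 0 <= self.caller["max_q0"] <= 1:
            raise ValueError("caller.max_q0 must be in [0, 1]")
        if self.caller["min_size"] < 0:
            raise ValueError("caller.min_size must be >= 0")
        if not 0 <= self.classify["deleted_below"] <= self.classify["duplicated_above"]:
            raise ValueError("classify bounds must satisfy 0 <= deleted_below <= duplicated_above")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _load_population(cfg: PipelineConfig) -> dict[str, str]:
    if cfg.simulate is not None:
        return {str(i): str(g) for i, g in cfg.simulate["individuals"]}
    import pandas as pd

    df = pd.read_csv(
        Path(cfg.inputs["groups_table"]), sep="\t", names=["individual", "group"]
    )
    return dict(zip(df["individual"].astype(str), df["group"].astype(str)))


def _design_from_section(cfg: PipelineConfig) -> tuple[_syn.GenomeLayout, _syn.PopulationDesign]:
    sim = dict(cfg.simulate)
    layout = _syn.make_layout(sim.pop("chromosomes"), cfg.window_size)
    sim["individuals"] = tuple((str(i), str(g)) for i, g in sim["individuals"])
    sim.setdefault("seed", cfg.seed)
    for key in ("cnv_length_range", "deletion_cn_choices", "duplication_cn_choices"):
        if key in sim:
            sim[key] = tuple(sim[key])
    known = set(_syn.PopulationDesign.__dataclass_fields__)
    unknown = set(sim) - known
    if unknown:
        raise ValueError(f"unknown keys in config section 'simulate': {sorted(unknown)}")
    return layout, _syn.PopulationDesign(**sim)


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute every configured stage, write stage outputs, return the manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "parameters": config.to_dict(),
        "stages": [],
    }

    def record(stage: str, **counts) -> None:
        manifest["stages"].append({"stage": stage, **counts})
        log.info("stage %s: %s", stage, counts)

    population = _load_population(config)
    profiles: dict[str, _syn.DepthProfile] = {}

    # --- simulate -----------------------------------------------------
    if config.simulate is not None:
        try:
            layout, design = _design_from_section(config)
            truth = _syn.plant_truth(layout, design)
            _syn.write_truth(truth, out / "truth.tsv")
            for ind in design.ids:
                profiles[ind] = _syn.simulate_depth(layout, truth, ind, design)
                _syn.write_depth_tracks(
                    profiles[ind],
                    out / f"{ind}.counts.bedgraph",
                    out / f"{ind}.q0.bedgraph",
                )
            record("simulate", individuals=len(profiles), truth_cnvs=len(truth))
        except Exception as exc:  # noqa: BLE001 - abort with stage context
            raise PipelineError("simulate", exc) from exc
    else:
        try:
            depth_dir = Path(config.inputs["depth_dir"])
            for ind in sorted(population):
                profiles[ind] = _syn.read_depth_tracks(
                    depth_dir / f"{ind}.counts.bedgraph",
                    depth_dir / f"{ind}.q0.bedgraph",
                    ind,
                )
            layout = next(iter(profiles.values())).layout
            record("load_depth", individuals=len(profiles))
        except Exception as exc:
            raise PipelineError("load_depth", exc) from exc

    # --- call + filter ------------------------------------------------
    cal = config.caller
    norm_tracks: dict[str, _caller.NormalizedRd] = {}
    raw_calls: list[_caller.CnvCall] = []
    try:
        for ind in sorted(profiles):
            norm = _caller.normalize(profiles[ind], trimmed=cal["trimmed_mean"])
            norm_tracks[ind] = norm
            segs = _caller.segment(
                norm,
                bandwidths=tuple(cal["bandwidths"]),
                t=cal["t"],
                merge_eps=cal["merge_eps"],
            )
            raw_calls.extend(
                _caller.call_from_segments(segs, norm, profiles[ind], cal["call_threshold"])
            )
        record("call", candidate_calls=len(raw_calls))
    except Exception as exc:
        raise PipelineError("call", exc) from exc

    try:
        calls = _caller.filter_calls(
            raw_calls, cal["pval"], cal["min_size"], cal["max_q0"]
        )
        _caller.write_calls(calls, out / "calls.tsv")
        record("filter", filtered_calls=len(calls))
    except Exception as exc:
        raise PipelineError("filter", exc) from exc

    # --- merge + classify ----------------------------------------------
    try:
        cnvrs = _cnvr.merge_calls(calls, population)
        record("merge", cnvrs=len(cnvrs))
    except Exception as exc:
        raise PipelineError("merge", exc) from exc

    try:
        classified = []
        for c in cnvrs:
            cls = _cnvr.classify_cnvr(
                c, config.classify["deleted_below"], config.classify["duplicated_above"]
            )
            classified.append(replace(c, region_type=cls.region_type))
        cnvrs = classified
        _cnvr.write_cnvrs(cnvrs, out / "cnvrs.tsv")
        record("classify", cnvrs=len(cnvrs))
    except Exception as exc:
        raise PipelineError("classify", exc) from exc

    # --- summarize -----------------------------------------------------
    try:
        summaries = [_cnvr.summarize(cnvrs, layout, scope="cohort")]
        presence = _cnvr.group_presence(cnvrs, population) if cnvrs else None
        if presence is not None:
            for g, ids in sorted(presence.per_group.items()):
                summaries.append(
                    _cnvr.summarize(
                        [c for c in cnvrs if c.id in ids], layout, scope=g
                    )
                )
        record("summarize", scopes=len(summaries))
    except Exception as exc:
        raise PipelineError("summarize", exc) from exc

    # --- compare -------------------------------------------------------
    overlap_reports: list[_overlap.OverlapReport] = []
    if config.compare:
        try:
            for ref in config.compare.get("references", []) or []:
                ref_set = _overlap.LabelledIntervalSet.read(
                    ref["path"], ref.get("name"), ref.get("dialect", "bed")
                )
                overlap_reports.append(_overlap.overlap_sets(cnvrs, ref_set))
            if config.compare.get("qtl"):
                q = config.compare["qtl"]
                qtl_set = _overlap.LabelledIntervalSet.read(
                    q["path"], q.get("name", "qtl"), q.get("dialect", "bed")
                )
                qtl_rep = _overlap.overlap_qtl(cnvrs, qtl_set)
                (out / "qtl.json").write_text(
                    json.dumps(
                        {
                            "n_cnvrs_associated": qtl_rep.n_cnvrs_associated,
                            "n_qtl_labels_hit": qtl_rep.n_qtl_labels_hit,
                            "label_counts": qtl_rep.label_counts,
                        },
                        indent=2,
                        sort_keys=True,
                    )
                )
            if config.compare.get("genes"):
                g = config.compare["genes"]
                gene_set = _overlap.LabelledIntervalSet.read(
                    g["path"], g.get("name", "genes"), g.get("dialect", "bed")
                )
                capture = _overlap.annotate_genes(
                    cnvrs, gene_set, g.get("min_fraction", 0.5)
                )
                (out / "genes.json").write_text(
                    json.dumps(
                        {k: round(v, 6) for k, v in sorted(capture.captured.items())},
                        indent=2,
                    )
                )
            record("compare", references=len(overlap_reports))
        except Exception as exc:
            raise PipelineError("compare", exc) from exc
    else:
        record("compare", references=0)

    # --- vst -----------------------------------------------------------
    vst_records: list[_vst.VstRecord] = []
    candidates: list[_vst.VstRecord] = []
    if config.vst["enabled"] and len(set(population.values())) == 2 and cnvrs:
        try:
            for c in cnvrs:
                vst_records.append(_vst.cnvr_vst(c, norm_tracks, population))
            candidates, threshold = _vst.select_candidates(
                vst_records, config.vst["mode"], config.vst["cutoff"]
            )
            _vst.write_vst_table(
                vst_records, {r.cnvr_id for r in candidates}, out / "vst.tsv"
            )
            record("vst", records=len(vst_records), candidates=len(candidates))
        except Exception as exc:
            raise PipelineError("vst", exc) from exc
    else:
        record("vst", records=0, candidates=0)

    # --- report ----------------------------------------------------------
    try:
        render_reports(summaries, overlap_reports, out)
        record("report", tables=1 + bool(overlap_reports))
    except Exception as exc:
        raise PipelineError("report", exc) from exc

    manifest["outputs"] = sorted(p.name for p in out.iterdir() if p.is_file())
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest


def render_reports(summaries, overlap_reports, out_dir) -> None:
    """Write the summary and overlap text tables for a finished run."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "summary.txt").write_text(_report.render_summary_table(summaries) + "\n")
    if overlap_reports:
        (out / "overlap.txt").write_text(
            _report.render_overlap_table(overlap_reports) + "\n"
        )


def run_qpcr_validation(
    ct_table_path, calibrator_sample: str, predicted: list[tuple[str, str, str]],
    mode: str = "majority", out_path=None,
):
    """Convenience: Ct table → copy numbers → concordance against predictions."""
    df = read_ct_table(ct_table_path)
    estimates = [
        copy_number_from_ddct(m) for m in build_measurements(df, calibrator_sample)
    ]
    qpcr_cns = [(e.target_id, e.sample_id, e.cn) for e in estimates]
    report = concordance(predicted, qpcr_cns, mode=mode)
    if out_path is not None:
        import pandas as pd

        rows = [
            (e.target_id, e.sample_id, f"{e.dct_test:.4f}", f"{e.dct_calibrator:.4f}",
             f"{e.ddct:.4f}", f"{e.cn:.4f}")
            for e in estimates
        ]
        pd.DataFrame(
            rows, columns=["target", "sample", "dct_test", "dct_cal", "ddct", "cn"]
        ).to_csv(out_path, sep="\t", index=False)
    return estimates, report
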