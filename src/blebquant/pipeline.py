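"""End-to-end assay orchestration from a single run configuration.

``run_assay`` executes the full workflow — read or generate fields,
segment nuclei, filter by area, build ring masks, call the four markers,
summarise each field, compare groups — and writes a per-cell CSV, a
per-field summary CSV, a comparisons JSON and a run log to the output
directory.  A provenance block (config hash, seed, software version) makes
runs auditable; two runs with the same config and seed produce identical
output files.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .assay_stats import (
    FIELD_METRICS,
    FieldSummary,
    GroupComparison,
    compare_groups,
    summarize_field,
)
from .field_io import (
    CELL_TABLE_COLUMNS,
    CalibratedField,
    ChannelMap,
    read_field,
    resolve_microns_per_pixel,
    write_cell_table,
)
from .marker_calls import (
    SpotParams,
    auto_background_threshold,
    auto_threshold_gh2ax,
    build_cell_calls,
    classify_cytoplasmic_cc3,
    classify_gh2ax,
    count_puncta,
    detect_cc3_puncta,
    ring_owner_map,
)
from .segmentation import (
    RING_WIDTH_BOUNDS_UM,
    SegmentationParams,
    auto_select_ring_width,
    filter_nuclei_by_area,
    make_cytoplasm_rings,
    segment_nuclei,
)
from .synthetic_fields import SyntheticConfig, generate_study

logger = logging.getLogger("blebquant")


def packaged_config_path(name: str = "synthetic_study.yaml") -> Path:
    """Path to a study configuration shipped with the package."""
    from importlib.resources import files

    return Path(str(files("blebquant") / "configs" / name))


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    """Validated run configuration (usually parsed from YAML).

    Exactly one of ``inputs`` (a manifest of TIFF paths with group labels)
    or ``synthetic`` (a generated-study specification) must be present.
    """

    seed: int = 0
    output_dir: str = "blebquant_out"
    calibration: float = 0.4622
    calibration_unit: str = "um_per_px"
    channel_map: dict[int, str] = dc_field(
        default_factory=lambda: {0: "DAPI", 1: "CC3", 2: "GH2AX"}
    )
    inputs: list[dict] | None = None
    synthetic: dict | None = None
    segmentation: dict = dc_field(default_factory=dict)
    min_nucleus_area_um2: float = 50.0
    max_nucleus_area_um2: float = 200.0
    ring_width_um: float | str = "auto"
    spots: dict = dc_field(default_factory=dict)
    cyto_cc3_threshold: float | str = 2600.0
    gh2ax_threshold: float | str = "auto"
    comparisons: list[dict] = dc_field(default_factory=list)
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def canonical_dict(self) -> dict:
        return dataclasses.asdict(self)

    def sha256(self) -> str:
        """Hash of the analysis-relevant configuration.

        Excludes run-local fields (output directory, log level) so that
        re-running the same analysis elsewhere yields the same identity.
        """
        payload = self.canonical_dict()
        payload.pop("output_dir", None)
        payload.pop("log_level", None)
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()


def _spot_params(cfg: RunConfig) -> SpotParams:
    raw = dict(cfg.spots)
    raw.setdefault("spot_intensity_threshold", raw.pop("intensity_threshold", 4000.0))
    return SpotParams(**raw)


def _seg_params(cfg: RunConfig) -> SegmentationParams:
    return SegmentationParams(**cfg.segmentation)


def validate_config(cfg: RunConfig) -> list[str]:
    """Return a list of human-readable violations; empty means valid."""
    violations: list[str] = []
    if (cfg.inputs is None) == (cfg.synthetic is None):
        violations.append("exactly one of 'inputs' or 'synthetic' must be present")
    if cfg.calibration <= 0:
        violations.append(f"calibration must be positive, got {cfg.calibration}")
    if cfg.calibration_unit not in ("um_per_px", "um2_per_px"):
        violations.append(f"calibration_unit must be um_per_px or um2_per_px, got {cfg.calibration_unit!r}")
    try:
        ChannelMap(cfg.channel_map)
    except ValueError as exc:
        violations.append(f"channel_map: {exc}")
    if not cfg.min_nucleus_area_um2 < cfg.max_nucleus_area_um2:
        violations.append(
            "nucleus area window inverted: "
            f"min {cfg.min_nucleus_area_um2} >= max {cfg.max_nucleus_area_um2}"
        )
    lo, hi = RING_WIDTH_BOUNDS_UM
    if cfg.ring_width_um != "auto" and not lo <= float(cfg.ring_width_um) <= hi:
        violations.append(
            f"ring_width_um {cfg.ring_width_um} outside the [{lo}, {hi}] um bound"
        )
    try:
        _spot_params(cfg)
    except ValueError as exc:
        violations.append(f"SpotParams: {exc}")
    try:
        _seg_params(cfg)
    except TypeError as exc:
        violations.append(f"segmentation: {exc}")
    if cfg.inputs is not None:
        for entry in cfg.inputs:
            p = entry.get("path")
            if not p or not Path(p).exists():
                violations.append(f"input field not found: {p}")
            if not entry.get("group"):
                violations.append(f"input {p} has no group label")
    if cfg.synthetic is not None:
        try:
            _synthetic_groups(cfg)
        except (ValueError, TypeError) as exc:
            violations.append(f"synthetic: {exc}")
    for comp in cfg.comparisons:
        metric = comp.get("metric")
        if metric not in FIELD_METRICS:
            violations.append(f"comparison metric {metric!r} not one of {FIELD_METRICS}")
        if not comp.get("a") or not comp.get("b"):
            violations.append(f"comparison {comp} missing group names")
    return violations


def _synthetic_groups(cfg: RunConfig) -> tuple[list[tuple[str, SyntheticConfig]], int]:
    spec = dict(cfg.synthetic or {})
    fields_per_group = int(spec.pop("fields_per_group", 6))
    group_specs = spec.pop("groups", None)
    if not group_specs:
        raise ConfigError("synthetic spec needs a non-empty 'groups' list")
    base = dict(spec)
    base.setdefault("microns_per_pixel", resolve_microns_per_pixel(cfg.calibration, cfg.calibration_unit))
    if "field_px" in base:
        base["field_px"] = tuple(base["field_px"])
    groups = []
    for g in group_specs:
        g = dict(g)
        label = g.pop("label", None)
        if not label:
            raise ConfigError("every synthetic group needs a 'label'")
        merged = {**base, **g}
        if "field_px" in merged:
            merged["field_px"] = tuple(merged["field_px"])
        scfg = SyntheticConfig(**merged)
        scfg.validate()
        groups.append((label, scfg))
    return groups, fields_per_group


@dataclass
class FieldResult:
    """Per-field analysis output: calls, summary and auditable diagnostics."""

    field_id: str
    group_label: str
    calls: list
    summary: FieldSummary | None
    diagnostics: dict


def analyze_field(
    cal_field: CalibratedField,
    seg_params: SegmentationParams | None = None,
    min_nucleus_area_um2: float = 50.0,
    max_nucleus_area_um2: float = 200.0,
    ring_width_um: float | str = "auto",
    spot_params: SpotParams | None = None,
    cyto_cc3_threshold: float | str = 2600.0,
    gh2ax_threshold: float | str = "auto",
) -> FieldResult:
    """Run the full per-field workflow: segment, ring, call, summarise."""
    spot_params = spot_params or SpotParams()
    mpp = cal_field.microns_per_pixel
    diagnostics: dict[str, Any] = {"field_id": cal_field.field_id}

    label_map = segment_nuclei(cal_field.channels["DAPI"], mpp, seg_params)
    diagnostics["n_segmented"] = label_map.n_nuclei
    label_map = filter_nuclei_by_area(label_map, min_nucleus_area_um2, max_nucleus_area_um2)
    diagnostics["n_area_filtered_out"] = diagnostics["n_segmented"] - label_map.n_nuclei
    diagnostics["n_retained"] = label_map.n_nuclei
    group = cal_field.group_label or ""
    if label_map.n_nuclei == 0:
        diagnostics["excluded_reason"] = "zero retained nuclei"
        return FieldResult(cal_field.field_id, group, [], None, diagnostics)

    if ring_width_um == "auto":
        width = auto_select_ring_width(label_map)
    else:
        width = float(ring_width_um)
    diagnostics["ring_width_um"] = width
    cells = make_cytoplasm_rings(label_map, width)

    cc3 = cal_field.channels["CC3"]
    if cyto_cc3_threshold == "auto":
        cyto_thr = auto_background_threshold(cc3, ring_owner_map(cells))
    else:
        cyto_thr = float(cyto_cc3_threshold)
    diagnostics["cyto_cc3_threshold"] = cyto_thr
    cyto_means, cyto_pos, unevaluable = classify_cytoplasmic_cc3(cells, cc3, cyto_thr)
    diagnostics["n_empty_ring_excluded"] = len(unevaluable)
    if unevaluable:
        logger.warning(
            "field %s: %d cell(s) with empty ring masks excluded from denominators",
            cal_field.field_id,
            len(unevaluable),
        )
    if not cyto_means:
        diagnostics["excluded_reason"] = "all rings empty"
        return FieldResult(cal_field.field_id, group, [], None, diagnostics)

    puncta = detect_cc3_puncta(cells, cc3, spot_params, mpp)
    counts = count_puncta(puncta, cells)
    diagnostics["n_puncta"] = len(puncta)

    gh_means, _ = classify_gh2ax(label_map, cal_field.channels["GH2AX"], 0.0)
    if gh2ax_threshold == "auto":
        values = list(gh_means.values())
        gh_thr = auto_threshold_gh2ax(values) if len(values) >= 2 else float(max(values))
    else:
        gh_thr = float(gh2ax_threshold)
    diagnostics["gh2ax_threshold"] = gh_thr
    gh_pos = {lab: m > gh_thr for lab, m in gh_means.items()}

    calls = build_cell_calls(
        cells, cyto_means, cyto_pos, counts, gh_means, gh_pos,
        min_puncta=spot_params.min_puncta_per_cell,
    )
    summary = summarize_field(calls, cal_field.field_id, group)
    return FieldResult(cal_field.field_id, group, calls, summary, diagnostics)


def _calls_to_frame(results: list[FieldResult]) -> pd.DataFrame:
    rows = []
    for res in results:
        for c in res.calls:
            rows.append(
                {
                    "field_id": res.field_id,
                    "cell_label": c.cell_label,
                    "nuclear_area_um2": c.nuclear_area_um2,
                    "cyto_cc3_mean": c.cyto_cc3_mean,
                    "cyto_cc3_pos": c.cyto_cc3_pos,
                    "puncta_count": c.puncta_count,
                    "cc3_bleb_pos": c.cc3_bleb_pos,
                    "gh2ax_mean": c.gh2ax_mean,
                    "gh2ax_pos": c.gh2ax_pos,
                    "coloc_pos": c.coloc_pos,
                }
            )
    if not rows:
        return pd.DataFrame(columns=CELL_TABLE_COLUMNS)
    return pd.DataFrame(rows, columns=CELL_TABLE_COLUMNS)


def _load_fields(cfg: RunConfig) -> list[CalibratedField]:
    mpp = resolve_microns_per_pixel(cfg.calibration, cfg.calibration_unit)
    if cfg.inputs is not None:
        cmap = ChannelMap(cfg.channel_map)
        return [
            read_field(e["path"], cmap, mpp, group_label=e["group"])
            for e in cfg.inputs
        ]
    groups, fields_per_group = _synthetic_groups(cfg)
    study = generate_study(groups, fields_per_group, master_seed=cfg.seed)
    return [f for f, _truth in study]


def run_assay(cfg: RunConfig, seed: int | None = None) -> dict:
    """Execute the configured assay end to end and write run artifacts.

    Returns a dict with the output paths, the per-field summaries and the
    group comparisons.  Raises :class:`ConfigError` on an invalid config.
    """
    violations = validate_config(cfg)
    if violations:
        raise ConfigError("invalid config: " + "; ".join(violations))
    if seed is not None:
        cfg = dataclasses.replace(cfg, seed=int(seed))

    out_dir = Path(cfg.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out_dir / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(getattr(logging, cfg.log_level.upper(), logging.INFO))
    try:
        logger.info("blebquant %s starting; config sha256=%s seed=%d", __version__, cfg.sha256(), cfg.seed)
        fields = _load_fields(cfg)
        logger.info("%d field(s) loaded", len(fields))

        seg_params = _seg_params(cfg)
        spot_params = _spot_params(cfg)
        results: list[FieldResult] = []
        for f in fields:
            res = analyze_field(
                f,
                seg_params=seg_params,
                min_nucleus_area_um2=cfg.min_nucleus_area_um2,
                max_nucleus_area_um2=cfg.max_nucleus_area_um2,
                ring_width_um=cfg.ring_width_um,
                spot_params=spot_params,
                cyto_cc3_threshold=cfg.cyto_cc3_threshold,
                gh2ax_threshold=cfg.gh2ax_threshold,
            )
            if res.summary is None:
                logger.warning(
                    "field %s excluded from statistics: %s",
                    res.field_id,
                    res.diagnostics.get("excluded_reason"),
                )
            else:
                logger.info(
                    "field %s (%s): %d cells, ring %.0f um, puncta %d",
                    res.field_id,
                    res.group_label,
                    res.summary.n_cells,
                    res.diagnostics["ring_width_um"],
                    res.diagnostics["n_puncta"],
                )
            results.append(res)

        cells_df = _calls_to_frame(results)
        cells_path = out_dir / "cells.csv"
        write_cell_table(cells_df, cells_path)

        summaries = [r.summary for r in results if r.summary is not None]
        fields_df = pd.DataFrame([s.as_dict() for s in summaries])
        fields_path = out_dir / "fields.csv"
        fields_df.to_csv(fields_path, index=False)

        comparisons: list[GroupComparison] = []
        for comp in cfg.comparisons:
            comparisons.append(compare_groups(summaries, comp["a"], comp["b"], comp["metric"]))
            logger.info(
                "comparison %s vs %s on %s: U=%.1f p=%.3g %s",
                comp["a"], comp["b"], comp["metric"],
                comparisons[-1].u_statistic, comparisons[-1].p_value, comparisons[-1].stars,
            )

        provenance = {
            "software": "blebquant",
            "version": __version__,
            "config_sha256": cfg.sha256(),
            "seed": cfg.seed,
        }
        comp_path = out_dir / "comparisons.json"
        with open(comp_path, "w") as fh:
            json.dump(
                {
                    "provenance": provenance,
                    "comparisons": [c.as_dict() for c in comparisons],
                    "diagnostics": [_jsonable(r.diagnostics) for r in results],
                },
                fh,
                indent=2,
            )
        return {
            "cells_csv": cells_path,
            "fields_csv": fields_path,
            "comparisons_json": comp_path,
            "results": results,
            "summaries": summaries,
            "comparisons": comparisons,
            "provenance": provenance,
        }
    finally:
        logger.removeHandler(handler)
        handler.close()


def _jsonable(d: dict) -> dict:
    out = {}
    for k, v in d.items():
        if isinstance(v, (np.integer,)):
            v = int(v)
        elif isinstance(v, (np.floating,)):
            v = float(v)
        out[k] = v
    return out
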