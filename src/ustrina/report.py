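"""Full-analysis orchestration and reporting.

``run_analysis`` chains every stage — totals and composition shares,
fragmentation and cranial/post-cranial indices, spatial summaries
(hotspots, core region, peripheral clusters, transects through the peak
square), and the weight-budget MNI solutions for a set of demographic
scenarios — into one deterministic, JSON-serialisable report.  Every
number in the report is recomputable from the input deposit and the
configuration alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from importlib import metadata
from pathlib import Path
from typing import Optional, Sequence

from . import spatial
from .budget import DemographicScenario, salorno_scenarios, solve_mni
from .deposit import Deposit
from .indices import (
    composition_shares,
    deposit_cpc_index,
    deposit_fragmentation_index,
    round_half_up,
)

logger = logging.getLogger("ustrina")

SCHEMA_VERSION = "1.0"

#: Minimal structural schema of the JSON report: required key -> type.
#: Shipped alongside as configs/report.schema.json for external tooling.
_REPORT_SCHEMA: dict[str, type] = {
    "schema_version": str,
    "provenance": dict,
    "totals": dict,
    "composition_shares_pct": dict,
    "indices": dict,
    "spatial": dict,
    "mni": list,
}


def validate_report(report: dict) -> None:
    """Check the report against the shipped structural schema; raise on failure."""
    for key, typ in _REPORT_SCHEMA.items():
        if key not in report:
            raise ValueError(f"report missing required key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(
                f"report key {key!r} must be {typ.__name__}, got {type(report[key]).__name__}"
            )


def _file_sha256(path) -> Optional[str]:
    try:
        return hashlib.sha256(Path(path).read_bytes()).hexdigest()
    except (OSError, TypeError):
        return None


def run_analysis(
    deposit: Deposit,
    *,
    scenarios: Optional[Sequence[DemographicScenario]] = None,
    us: Optional[int] = None,
    top_k: int = 5,
    core_fraction: float = 0.10,
    connectivity: int = 8,
    input_path=None,
    seed: Optional[int] = None,
) -> dict:
    """Run the full quantitative analysis of a deposit.

    ``us`` scopes the spatial stages to one stratigraphic unit (all cuts
    plus its surface layer); totals and budget solving always use the
    whole deposit.  ``scenarios`` defaults to the three shipped reference
    scenarios.  The result is a plain dict (see ``validate_report`` for
    its contract) that serialises to byte-identical JSON across runs.
    """
    t0 = time.perf_counter()
    scenarios = list(scenarios) if scenarios is not None else salorno_scenarios()
    total = deposit.total_weight()

    logger.info("totals stage")
    totals = {
        "total_g": total,
        "by_us": {str(k): v for k, v in deposit.aggregate("us").items()},
        "n_records": len(deposit.records),
    }
    shares = composition_shares(deposit) if total > 0 else {}

    logger.info("indices stage")
    frag = deposit_fragmentation_index(deposit)
    cpc = deposit_cpc_index(deposit)
    w_c = deposit.total_weight(region="cranial")
    w_p = deposit.total_weight(region="postcranial")
    indices_block = {
        "fragmentation_index": frag.as_dict(),
        "cpc_index": cpc.as_dict(),
        "cranial_share_pct": (
            round_half_up(w_c / (w_c + w_p) * 100.0, 3) if (w_c + w_p) > 0 else None
        ),
    }

    logger.info("spatial stage")
    gm = spatial.weight_map(deposit, us=us)
    spatial_block: dict = {"us_filter": us, "map_total_g": gm.total()}
    if gm.total() > 0:
        hotspots = spatial.top_squares(gm, top_k)
        core = spatial.detect_core(gm, fraction=core_fraction)
        clusters = spatial.peripheral_clusters(gm, core, connectivity=connectivity)
        peak = hotspots[0][0]
        ci, cj = gm.centroid()
        spatial_block.update(
            {
                "hotspots": [
                    {"square": sq.label, "weight_g": w} for sq, w in hotspots
                ],
                "centroid": {"row_index": ci, "column_index": cj},
                "core": {
                    "members": core.labels,
                    "total_g": core.total,
                    "mean_per_square_g": core.mean_per_square,
                    "extent_m": list(core.extent),
                },
                "clusters": [
                    {
                        "members": r.labels,
                        "total_g": r.total,
                        "fragmentation_index": (
                            r.fragmentation.as_dict() if r.fragmentation else None
                        ),
                    }
                    for r in clusters
                ],
                "transects": {
                    "row": {
                        "label": peak.row,
                        "values_g": list(spatial.transect(gm, "row", peak.row)),
                    },
                    "column": {
                        "label": peak.column,
                        "values_g": list(spatial.transect(gm, "column", peak.column)),
                    },
                },
            }
        )

    logger.info("budget stage")
    mni_block = [solve_mni(s, total).as_dict() for s in scenarios]

    try:
        version = metadata.version("ustrina")
    except metadata.PackageNotFoundError:  # pragma: no cover
        version = "unknown"
    report = {
        "schema_version": SCHEMA_VERSION,
        "provenance": {
            "tool": "ustrina",
            "version": version,
            "input_sha256": _file_sha256(input_path) if input_path else None,
            "seed": seed,
            "config": {
                "us_filter": us,
                "top_k": top_k,
                "core_fraction": core_fraction,
                "connectivity": connectivity,
                "scenarios": [s.label for s in scenarios],
            },
        },
        "totals": totals,
        "composition_shares_pct": shares,
        "indices": indices_block,
        "spatial": spatial_block,
        "mni": mni_block,
    }
    validate_report(report)
    logger.info("analysis finished in %.3f s", time.perf_counter() - t0)
    return report


def report_to_json(report: dict, path=None) -> str:
    """Serialise the report deterministically (sorted keys, fixed separators)."""
    text = json.dumps(report, indent=2, sort_keys=True, allow_nan=False, default=_jsonify)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def _jsonify(obj):
    import numpy as np

    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    raise TypeError(f"not JSON serialisable: {type(obj)!r}")


def format_text_report(report: dict) -> str:
    """Human-readable summary of the main report numbers."""
    lines = [
        "Cremation-deposit analysis",
        f"  total weight: {report['totals']['total_g']:,.1f} g "
        f"({report['totals']['n_records']} records)",
    ]
    shares = report.get("composition_shares_pct") or {}
    if shares:
        lines.append(
            "  composition: "
            + "  ".join(f"{k} {round_half_up(v, 1):.1f}%" for k, v in shares.items())
        )
    frag = report["indices"]["fragmentation_index"]
    cpc = report["indices"]["cpc_index"]
    if frag["defined"]:
        lines.append(f"  fragmentation index: {round_half_up(frag['value'], 1):.1f}")
    if cpc["defined"]:
        lines.append(f"  CPC index: {round_half_up(cpc['value'], 1):.1f}")
    sp = report["spatial"]
    if sp.get("hotspots"):
        tops = ", ".join(f"{h['square']} ({h['weight_g']:,.1f} g)" for h in sp["hotspots"][:3])
        lines.append(f"  hotspots: {tops}")
        lines.append(
            f"  core: {len(sp['core']['members'])} squares, "
            f"{sp['core']['total_g']:,.1f} g, mean {sp['core']['mean_per_square_g']:,.1f} g"
        )
        lines.append(f"  peripheral clusters: {len(sp['clusters'])}")
    lines.append("  MNI solutions:")
    for sol in report["mni"]:
        lines.append(
            f"    {sol['scenario']}: MNI {sol['mni']} "
            f"(units {sol['unit_count']}, modelled {sol['modelled_g']:,.1f} g, "
            f"misfit {sol['misfit_g']:+,.1f} g)"
        )
    return "\n".join(lines)
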