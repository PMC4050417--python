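"""The two planning workflows and the comparison report.

Gated workflow: estimate the individualized threshold on the reference gated
phase, segment all six phases, match lesions across phases, union each
lesion's per-phase BTVs into its BITV, and expand by the 3 mm isotropic
set-up margin into the PTVg.

Non-gated workflow: same threshold protocol on the time-averaged exam, keep
the seeded/supplied lesion BTV, derive a CTV (a supplied manual mask when
given — the faithful path — else the BTV clipped to the liver as an
automation stand-in for the clinician's edit), and expand by 5 mm radial /
10 mm craniocaudal into the conventional PTV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .geometry import BinaryMask, GatedSeries, SUVImage, volume_cc
from .margins import MarginSpec, expand
from .segment import (
    LesionCorrespondence,
    LesionSet,
    build_bitv,
    label_lesions,
    match_lesions,
    segment_series,
    threshold_segment,
)
from .stats import VolumeRecord, summarize, wilcoxon_exact
from .suv import BackgroundEstimate, estimate_threshold

__all__ = [
    "PipelineConfig",
    "GatedResult",
    "NongatedResult",
    "run_gated_workflow",
    "run_nongated_workflow",
    "compare_report",
]


@dataclass(frozen=True)
class PipelineConfig:
    """Protocol parameters of the delineation pipeline.

    Defaults follow the clinical protocol: 6 phases, 3 mm isotropic gated
    set-up margin, 5 mm radial / 10 mm craniocaudal conventional margin,
    0.1 cc minimum lesion volume, 15 mm lesion capture radius. The
    reference phase (used for threshold estimation, chosen in the clinic to
    match the planning CT's respiratory phase) is explicit configuration.
    """

    n_phases: int = 6
    reference_phase: int = 0
    ptvg_margin_mm: float = 3.0
    ptv_radial_mm: float = 5.0
    ptv_craniocaudal_mm: float = 10.0
    min_lesion_volume_cc: float = 0.1
    capture_radius_mm: float = 15.0
    roi_volume_cc: float = 25.0
    seed: int = 0

    @property
    def ptvg_margin(self) -> MarginSpec:
        return MarginSpec.iso(self.ptvg_margin_mm)

    @property
    def ptv_margin(self) -> MarginSpec:
        return MarginSpec(self.ptv_radial_mm, self.ptv_craniocaudal_mm)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        """Load pipeline parameters from a YAML (or JSON) mapping; keys match
        the field names and missing keys keep the protocol defaults."""
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        valid = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


@dataclass
class GatedResult:
    threshold: BackgroundEstimate
    phase_sets: list[LesionSet]
    correspondence: LesionCorrespondence
    bitv: dict[int, BinaryMask]
    ptvg: dict[int, BinaryMask]

    def volumes(self) -> dict[int, dict[str, float]]:
        return {
            lid: {"bitv_cc": volume_cc(self.bitv[lid]), "ptvg_cc": volume_cc(self.ptvg[lid])}
            for lid in sorted(self.bitv)
        }


def run_gated_workflow(
    series: GatedSeries,
    liver_mask: BinaryMask,
    config: PipelineConfig = PipelineConfig(),
    threshold: float | None = None,
) -> GatedResult:
    """Threshold (from the reference phase) -> per-phase BTVs -> lesion
    matching -> per-lesion BITV -> PTVg.

    ``threshold`` overrides the background protocol when the clinically
    measured value is already known.
    """
    if series.n_phases != config.n_phases:
        raise ValueError(
            f"series has {series.n_phases} phases, config expects {config.n_phases}"
        )
    if not 0 <= config.reference_phase < series.n_phases:
        raise ValueError(f"reference phase {config.reference_phase} out of range")
    if threshold is None:
        est = estimate_threshold(
            series[config.reference_phase], liver_mask, config.roi_volume_cc, config.seed
        )
    else:
        est = BackgroundEstimate([float(threshold)], float(threshold), 1)
    phase_sets = segment_series(series, est.threshold, config.min_lesion_volume_cc)
    corr = match_lesions(phase_sets, config.capture_radius_mm)
    bitv = {lid: build_bitv(corr, phase_sets, lid) for lid in corr.lesion_ids}
    ptvg = {lid: expand(m, config.ptvg_margin) for lid, m in bitv.items()}
    return GatedResult(est, phase_sets, corr, bitv, ptvg)


@dataclass
class NongatedResult:
    threshold: BackgroundEstimate
    btv: dict[int, BinaryMask]
    ctv: dict[int, BinaryMask]
    ptv: dict[int, BinaryMask]

    def volumes(self) -> dict[int, dict[str, float]]:
        return {
            lid: {
                "btv_cc": volume_cc(self.btv[lid]),
                "ctv_cc": volume_cc(self.ctv[lid]),
                "ptv_cc": volume_cc(self.ptv[lid]),
            }
            for lid in sorted(self.btv)
        }


def run_nongated_workflow(
    nongated: SUVImage,
    liver_mask: BinaryMask,
    config: PipelineConfig = PipelineConfig(),
    threshold: float | None = None,
    ctv_override: dict[int, BinaryMask] | None = None,
) -> NongatedResult:
    """Non-gated threshold -> lesion BTVs -> CTV -> anisotropic PTV.

    When ``ctv_override`` maps lesion ids to manually edited CTV masks those
    are expanded as-is; otherwise each CTV is the BTV intersected with the
    liver mask (automating the clinician's exclusion of lung/bone uptake).
    """
    if threshold is None:
        est = estimate_threshold(nongated, liver_mask, config.roi_volume_cc, config.seed)
    else:
        est = BackgroundEstimate([float(threshold)], float(threshold), 1)
    lset = label_lesions(
        threshold_segment(nongated, est.threshold), config.min_lesion_volume_cc, nongated
    )
    btv = {l.label: lset.mask_for(l.label) for l in lset}
    ctv: dict[int, BinaryMask] = {}
    for lid, m in btv.items():
        if ctv_override and lid in ctv_override:
            ctv[lid] = ctv_override[lid]
        else:
            ctv[lid] = m.intersection(liver_mask)
    ptv = {lid: expand(m, config.ptv_margin) for lid, m in ctv.items()}
    return NongatedResult(est, btv, ctv, ptv)


def _round_vol(v: float) -> float:
    return round(v, 1)


def compare_report(records: list[VolumeRecord]) -> dict:
    """Per-lesion PTV/PTVg and BITV/BTV comparison in the cohort-table layout.

    Volumes are reported in cc at 1 decimal and ratios as integer percent;
    the summary row carries means, SDs, ratio-of-means and the exact paired
    Wilcoxon p-values for PTV vs PTVg and BITV vs BTV.
    """
    if not records:
        raise ValueError("no records to report")
    rows = []
    for r in records:
        rows.append(
            {
                "patient": r.patient,
                "lesion": r.lesion,
                "ptv_cc": _round_vol(r.ptv_cc),
                "ptvg_cc": _round_vol(r.ptvg_cc),
                "ptv_over_ptvg_pct": int(round(100.0 * r.ptv_cc / r.ptvg_cc)) if r.ptvg_cc else None,
                "bitv_cc": _round_vol(r.bitv_cc),
                "btv_cc": _round_vol(r.btv_cc),
                "bitv_over_btv_pct": int(round(100.0 * r.bitv_cc / r.btv_cc)) if r.btv_cc else None,
                "ctv_cc": _round_vol(r.ctv_cc) if r.ctv_cc is not None else None,
                "liver_cc": _round_vol(r.liver_cc) if r.liver_cc is not None else None,
            }
        )
    summ = summarize(records)
    w_ptv = wilcoxon_exact([r.ptv_cc for r in records], [r.ptvg_cc for r in records])
    w_bitv = wilcoxon_exact([r.bitv_cc for r in records], [r.btv_cc for r in records])
    return {
        "rows": rows,
        "summary": {
            "mean_ptv_cc": summ["columns"]["ptv_cc"]["mean"],
            "sd_ptv_cc": summ["columns"]["ptv_cc"]["sd"],
            "mean_ptvg_cc": summ["columns"]["ptvg_cc"]["mean"],
            "sd_ptvg_cc": summ["columns"]["ptvg_cc"]["sd"],
            "mean_bitv_cc": summ["columns"]["bitv_cc"]["mean"],
            "sd_bitv_cc": summ["columns"]["bitv_cc"]["sd"],
            "mean_btv_cc": summ["columns"]["btv_cc"]["mean"],
            "sd_btv_cc": summ["columns"]["btv_cc"]["sd"],
            "ratio_of_means_ptv_over_ptvg_pct": int(round(summ["ratio_of_means_pct"]["ptv_over_ptvg"])),
            "ratio_of_means_bitv_over_btv_pct": int(round(summ["ratio_of_means_pct"]["bitv_over_btv"])),
        },
        "wilcoxon": {
            "ptv_vs_ptvg": {"p": w_ptv.p_value, "W": w_ptv.statistic, "n": w_ptv.n_nonzero,
                            "method": w_ptv.method, "degenerate": w_ptv.degenerate},
            "bitv_vs_btv": {"p": w_bitv.p_value, "W": w_bitv.statistic, "n": w_bitv.n_nonzero,
                            "method": w_bitv.method, "degenerate": w_bitv.degenerate},
        },
        "n_lesions": len(records),
    }


def write_report(report: dict, path) -> None:
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, allow_nan=False, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    raise TypeError(f"not JSON serializable: {type(o)}")
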