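"""YAML configuration for the screening funnel.

A config file carries up to four blocks::

    funnel:
      stages: [dedupe, stability, efficacy, diversity]
      target_count: 60
    stability:
      pH: 7.4
      max_cleavage_sites: 0
      scan_mode: position_anchored
      net_charge: {min: -10, max: 10}
      gravy_max: 0.5
      helix_propensity_min: -0.6
    efficacy:
      min_tm: 0.9
      max_ca_rmsd: 0.55
      min_mean_plddt: 80.0
      max_interface_pae: 6.0
    diversity:
      target_count: 60
      representative_rule: max_recovery
      patent_max_identity: 0.90
      distance_correction: none

Every key is optional; omitted values fall back to the library defaults
(cleavage cap 0, physicochemical bounds report-only).
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .funnel import FunnelConfig
from .stability import StabilityThresholds
from .structure import EfficacyThresholds

__all__ = ["load_config"]

_INF = float("inf")


def _stability_block(block: dict) -> tuple[StabilityThresholds, str]:
    charge = block.get("net_charge", {}) or {}
    thresholds = StabilityThresholds(
        max_cleavage_sites=int(block.get("max_cleavage_sites", 0)),
        net_charge_min=float(charge.get("min", -_INF)),
        net_charge_max=float(charge.get("max", _INF)),
        gravy_max=float(block.get("gravy_max", _INF)),
        helix_propensity_min=float(block.get("helix_propensity_min", -_INF)),
        pi_exclusion=(tuple(block["pi_exclusion"])
                      if "pi_exclusion" in block else None),
        pH=float(block.get("pH", 7.4)),
    )
    return thresholds, str(block.get("scan_mode", "position_anchored"))


def _efficacy_block(block: dict) -> EfficacyThresholds:
    def opt(key: str) -> float | None:
        return float(block[key]) if key in block else None

    return EfficacyThresholds(
        min_tm=opt("min_tm"),
        max_ca_rmsd=opt("max_ca_rmsd"),
        min_mean_plddt=opt("min_mean_plddt"),
        max_interface_pae=opt("max_interface_pae"),
        max_sap=opt("max_sap"),
        max_affinity=opt("max_affinity"),
    )


def load_config(path: str | Path) -> FunnelConfig:
    """Build a :class:`~pepfunnel.funnel.FunnelConfig` from a YAML file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    funnel_block = raw.get("funnel", {}) or {}
    stability, scan_mode = _stability_block(raw.get("stability", {}) or {})
    efficacy = (_efficacy_block(raw["efficacy"])
                if raw.get("efficacy") else None)
    diversity = raw.get("diversity", {}) or {}
    stages = tuple(funnel_block.get(
        "stages",
        ("dedupe", "stability") + (("efficacy",) if efficacy else ())
        + ("diversity",),
    ))
    return FunnelConfig(
        stages=stages,
        stability=stability,
        scan_mode=scan_mode,
        efficacy=efficacy,
        target_count=int(diversity.get(
            "target_count", funnel_block.get("target_count", 60))),
        representative_rule=str(
            diversity.get("representative_rule", "max_recovery")),
        patent_max_identity=float(
            diversity.get("patent_max_identity", 0.90)),
        distance_correction=str(
            diversity.get("distance_correction", "none")),
        missing_structure_policy=str(
            funnel_block.get("missing_structure_policy", "strict")),
        seed=int(funnel_block.get("seed", 0)),
    )
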