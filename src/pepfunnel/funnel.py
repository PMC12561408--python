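"""Funnel orchestration: gates in sequence, per-candidate scorecards,
stage counts, and the in-vitro bookkeeping computations.

The funnel runs the screening gates in the campaign order — deduplication,
stability, efficacy, diversity — and keeps strict count conservation at
every stage: candidates entering a stage either pass to the next or are
recorded as failures with machine-readable reasons, so
``entering(i+1) = passing(i)`` always holds.

The in-vitro bookkeeping mirrors the post-screening wet-lab accounting:
relative expression is the ratio of a fusion-peptide band density to the
reference band density; candidates on successful pulldown rows are dropped
when that ratio falls below a threshold (strict less-than: a value exactly
at the threshold proceeds); label tallies count assay outcomes.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from .diversity import (cut_clusters, identity_distance_matrix, nj_tree,
                        patent_gate, select_representatives)
from .peptide import PeptideRecord, TemplateSpec, dedupe, recovery
from .stability import (GateResult, PhysChemProfile, StabilityThresholds,
                        physchem_profile, scan_cleavage, stability_gate)
from .structure import (EfficacyThresholds, StructScore, StructureModel,
                        efficacy_gate)

__all__ = [
    "FunnelConfig", "CandidateScorecard", "StageSummary", "FunnelReport",
    "run_funnel", "funnel_counts", "relative_expression",
    "apply_expression_filter", "count_labels", "write_report",
    "load_assay_table", "load_bundled_assay_table",
]

KNOWN_STAGES = ("dedupe", "stability", "efficacy", "diversity")


@dataclass(frozen=True)
class FunnelConfig:
    """Configuration of a screening campaign.

    ``stages`` execute in order; ``target_count`` is the desired size of
    the final shortlist (the diversity stage cuts the tree into that many
    clusters).  No default stage is stochastic; ``seed`` is reserved for
    configured stochastic stages.
    """

    stages: tuple[str, ...] = KNOWN_STAGES
    stability: StabilityThresholds = field(
        default_factory=StabilityThresholds)
    scan_mode: str = "position_anchored"
    efficacy: EfficacyThresholds | None = None
    target_count: int = 60
    representative_rule: str = "max_recovery"
    patent_max_identity: float = 0.90
    distance_correction: str = "none"
    missing_structure_policy: str = "strict"  # or "lenient"
    agonist_chain: str = "A"
    receptor_chain: str = "B"
    seed: int = 0

    def __post_init__(self) -> None:
        seen = set()
        for s in self.stages:
            if s not in KNOWN_STAGES:
                raise ValueError(f"unknown stage {s!r}")
            if s in seen:
                raise ValueError(f"duplicate stage {s!r}")
            seen.add(s)
        if self.missing_structure_policy not in ("strict", "lenient"):
            raise ValueError("missing_structure_policy must be strict or "
                             "lenient")


@dataclass
class CandidateScorecard:
    """Everything measured about one candidate across the funnel."""

    id: str
    recovery: float | None = None
    physchem: PhysChemProfile | None = None
    cleavage_hits: tuple = ()
    struct_score: StructScore | None = None
    gate_results: dict[str, GateResult] = field(default_factory=dict)
    final_status: str = "pass"  # pass | fail | not_evaluated

    def as_row(self) -> dict:
        row: dict = {"id": self.id, "final_status": self.final_status,
                     "recovery": self.recovery}
        if self.physchem is not None:
            row.update(net_charge=self.physchem.net_charge,
                       pI=self.physchem.pI, gravy=self.physchem.gravy,
                       helix_propensity=self.physchem.helix_propensity)
        row["n_cleavage_hits"] = len(self.cleavage_hits)
        if self.struct_score is not None:
            s = self.struct_score
            row.update(tm=s.tm, ca_rmsd=s.ca_rmsd, mean_plddt=s.mean_plddt,
                       interface_pae=s.interface_pae,
                       sap_aggregate=s.sap_aggregate, affinity=s.affinity)
        for stage, res in self.gate_results.items():
            row[f"gate_{stage}"] = "pass" if res.passed else ";".join(
                str(r[0]) for r in res.reasons)
        return row


@dataclass(frozen=True)
class StageSummary:
    name: str
    n_in: int
    n_out: int
    failed: tuple[tuple[str, str], ...]  # (id, reason summary)


@dataclass
class FunnelReport:
    stages: list[StageSummary]
    scorecards: dict[str, CandidateScorecard]
    final_ids: list[str]

    def __post_init__(self) -> None:
        prev_out: int | None = None
        for s in self.stages:
            if prev_out is not None and s.n_in != prev_out:
                raise ValueError(
                    f"count conservation violated entering {s.name!r}")
            if s.n_in - s.n_out != len(s.failed):
                raise ValueError(f"pass+fail != in at stage {s.name!r}")
            prev_out = s.n_out


def run_funnel(candidates: list[PeptideRecord],
               template_spec: TemplateSpec,
               structures: dict[str, StructureModel] | None = None,
               pae: dict | None = None,
               affinity: dict[str, float] | None = None,
               config: FunnelConfig | None = None,
               struct_scores: dict[str, StructScore] | None = None,
               reference_structure: StructureModel | None = None
               ) -> FunnelReport:
    """Run the configured gates in order and account for every candidate.

    Structural inputs may come either precomputed (``struct_scores``, id ->
    :class:`~pepfunnel.structure.StructScore`) or raw (``structures`` as id
    -> model, ``pae`` as id -> PAE matrix, plus ``reference_structure`` for
    TM-score/RMSD).  In strict mode a configured efficacy stage with
    missing scores raises; lenient mode tags those candidates
    ``not_evaluated`` and passes them through with the annotation.
    """
    if not candidates:
        raise ValueError("no candidates")
    cfg = config or FunnelConfig()
    if struct_scores is None and structures is not None:
        if reference_structure is None:
            raise ValueError("scoring raw structures needs "
                             "reference_structure")
        from .structure import score_complex
        struct_scores = {
            cid: score_complex(
                model, reference_structure,
                pae=(pae or {}).get(cid),
                agonist_chain=cfg.agonist_chain,
                receptor_chain=cfg.receptor_chain,
                affinity=(affinity or {}).get(cid))
            for cid, model in structures.items()
        }
    template = template_spec.template

    cards: dict[str, CandidateScorecard] = {}
    for rec in candidates:
        cards[rec.id] = CandidateScorecard(
            id=rec.id,
            recovery=recovery(rec, template),
        )

    by_id = {rec.id: rec for rec in candidates}
    alive = [rec.id for rec in candidates]
    stages: list[StageSummary] = []

    def finish_stage(name: str, survivors: list[str],
                     failed: list[tuple[str, str]]) -> None:
        stages.append(StageSummary(name, len(alive), len(survivors),
                                   tuple(failed)))

    for stage in cfg.stages:
        failed: list[tuple[str, str]] = []
        survivors: list[str] = []

        if stage == "dedupe":
            unique, _ = dedupe([by_id[i] for i in alive])
            kept = {r.id for r in unique}
            first_of: dict[tuple[str, ...], str] = {}
            for i in alive:
                seq = by_id[i].residues
                if i in kept:
                    survivors.append(i)
                    first_of.setdefault(seq, i)
                else:
                    reason = f"duplicate_of:{first_of[seq]}"
                    failed.append((i, reason))
                    cards[i].gate_results[stage] = GateResult(
                        False, (("duplicate", i, first_of[seq]),))
                    cards[i].final_status = "fail"

        elif stage == "stability":
            for i in alive:
                rec = by_id[i]
                res = stability_gate(rec, cfg.stability,
                                     scan_mode=cfg.scan_mode)
                cards[i].gate_results[stage] = res
                cards[i].physchem = physchem_profile(rec, cfg.stability.pH)
                cards[i].cleavage_hits = tuple(
                    scan_cleavage(rec, mode=cfg.scan_mode))
                if res.passed:
                    survivors.append(i)
                else:
                    failed.append((i, ";".join(r[0] for r in res.reasons)))
                    cards[i].final_status = "fail"

        elif stage == "efficacy":
            if cfg.efficacy is None:
                raise ValueError("efficacy stage configured without "
                                 "thresholds")
            for i in alive:
                score = (struct_scores or {}).get(i)
                if score is None:
                    if cfg.missing_structure_policy == "strict":
                        raise ValueError(
                            f"candidate {i!r} has no structural scores "
                            "(strict mode)")
                    cards[i].final_status = "not_evaluated"
                    survivors.append(i)
                    continue
                if affinity and i in affinity:
                    score = StructScore(
                        tm=score.tm, ca_rmsd=score.ca_rmsd,
                        mean_plddt=score.mean_plddt,
                        interface_pae=score.interface_pae,
                        sap_aggregate=score.sap_aggregate,
                        affinity=affinity[i])
                cards[i].struct_score = score
                res = efficacy_gate(score, cfg.efficacy)
                cards[i].gate_results[stage] = res
                if res.passed:
                    survivors.append(i)
                else:
                    failed.append((i, ";".join(r[0] for r in res.reasons)))
                    cards[i].final_status = "fail"

        elif stage == "diversity":
            # patent-similarity cap first, then cluster representatives
            after_patent: list[str] = []
            for i in alive:
                res = patent_gate(by_id[i], template,
                                  cfg.patent_max_identity)
                cards[i].gate_results["patent"] = res
                if res.passed:
                    after_patent.append(i)
                else:
                    failed.append((i, "patent_identity"))
                    cards[i].final_status = "fail"
            k = min(cfg.target_count, len(after_patent))
            if len(after_patent) > k and len(after_patent) >= 3:
                dm = identity_distance_matrix(
                    [by_id[i] for i in after_patent],
                    correction=cfg.distance_correction)
                tree = nj_tree(dm)
                clusters = cut_clusters(tree, k)
                reps = set(select_representatives(
                    clusters, cfg.representative_rule,
                    recovery={i: cards[i].recovery for i in after_patent},
                    distances=dm))
                for i in after_patent:
                    if i in reps:
                        survivors.append(i)
                        cards[i].gate_results[stage] = GateResult(True)
                    else:
                        failed.append((i, "not_cluster_representative"))
                        cards[i].gate_results[stage] = GateResult(
                            False, (("not_cluster_representative", i, ""),))
                        cards[i].final_status = "fail"
            else:
                for i in after_patent:
                    survivors.append(i)
                    cards[i].gate_results[stage] = GateResult(True)

        finish_stage(stage, survivors, failed)
        alive = survivors

    return FunnelReport(stages=stages, scorecards=cards, final_ids=alive)


def funnel_counts(report: FunnelReport) -> list[tuple[str, int, int]]:
    """Per-stage (stage name, entering, passing) counts."""
    return [(s.name, s.n_in, s.n_out) for s in report.stages]


# --------------------------------------------------------------------------
# In-vitro bookkeeping

def relative_expression(peptide_band_density: float,
                        reference_band_density: float) -> float:
    """Fusion-peptide band density over the reference band density.

    Values above 1 are legitimate (the peptide can express better than the
    reference); nonpositive densities are rejected.
    """
    if peptide_band_density <= 0 or reference_band_density <= 0:
        raise ValueError("band densities must be positive")
    return peptide_band_density / reference_band_density


def load_assay_table(path: str | Path) -> pd.DataFrame:
    """Read an assay table TSV (columns: id, plus any of sequence_recovery,
    pulldown, relative_expression, kd_m, spr, ec50_nm, t_half_h)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns:
        raise ValueError(f"{path}: missing 'id' column")
    if df["id"].duplicated().any():
        raise ValueError(f"{path}: duplicate candidate ids")
    return df


def load_bundled_assay_table() -> pd.DataFrame:
    """The bundled in-vitro assay table for the 60-candidate campaign."""
    ref = resources.files("pepfunnel").joinpath("data/invitro_assays.tsv")
    with resources.as_file(ref) as path:
        return load_assay_table(path)


def apply_expression_filter(table: pd.DataFrame, threshold: float = 0.7
                            ) -> tuple[list[str], list[str]]:
    """Drop pulldown-successful candidates whose relative expression is
    below ``threshold`` (strict less-than: exactly-at-threshold proceeds).

    Returns (retained ids, excluded ids) over the Success rows only.
    """
    rows = table[table["pulldown"] == "Success"]
    if rows["relative_expression"].isna().any():
        bad = rows.loc[rows["relative_expression"].isna(), "id"].tolist()
        raise ValueError(f"missing relative expression on Success rows "
                         f"{bad}")
    excluded = rows.loc[rows["relative_expression"] < threshold,
                        "id"].tolist()
    retained = rows.loc[rows["relative_expression"] >= threshold,
                        "id"].tolist()
    return retained, excluded


def count_labels(table: pd.DataFrame, column: str, label: str) -> int:
    """Number of rows whose ``column`` equals ``label`` exactly."""
    if column not in table.columns:
        raise KeyError(f"unknown column {column!r}")
    return int((table[column] == label).sum())


# --------------------------------------------------------------------------
# Report serialization

def _report_payload(report: FunnelReport) -> dict:
    return {
        "stages": [
            {"name": s.name, "in": s.n_in, "out": s.n_out,
             "failed": [{"id": i, "reason": r} for i, r in s.failed]}
            for s in report.stages
        ],
        "final_ids": list(report.final_ids),
        "scorecards": [report.scorecards[i].as_row()
                       for i in sorted(report.scorecards)],
    }


def write_report(report: FunnelReport, path: str | Path,
                 format: str = "json") -> None:
    """Loss-free serialization with stable ordering (byte-deterministic
    for identical inputs).  Missing metrics serialize as nulls/empty cells,
    never zeros."""
    path = Path(path)
    if format == "json":
        path.write_text(json.dumps(_report_payload(report), indent=1,
                                   sort_keys=True, allow_nan=False,
                                   default=float) + "\n")
    elif format == "tsv":
        payload = _report_payload(report)
        df = pd.DataFrame(payload["scorecards"])
        cols = ["id", "final_status", "recovery", "net_charge", "pI",
                "gravy", "helix_propensity", "n_cleavage_hits", "tm",
                "ca_rmsd", "mean_plddt", "interface_pae", "sap_aggregate",
                "affinity"]
        ordered = [c for c in cols if c in df.columns] + \
                  sorted(c for c in df.columns if c not in cols)
        df[ordered].to_csv(path, sep="\t", index=False)
    else:
        raise ValueError(f"unknown report format {format!r}")
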