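"""Stability gate: proteolytic cleavage scanning and physicochemical scores.

GLP-1-class peptides are degraded in vivo by neutral endopeptidase
NEP-24.11, which attacks six dipeptide sites in the central and C-terminal
region of GLP-1(7-37).  The stability gate rejects designs that retain any
of these scissile dipeptides and reports solubility-related descriptors —
net charge at a stated pH, isoelectric point, hydropathy (GRAVY) and mean
helix propensity — against configurable bounds.

Net charge follows the Henderson–Hasselbalch form: each basic group
contributes ``1/(1+10^(pH-pKa))`` and each acidic group
``-1/(1+10^(pKa-pH))``; termini are included.  The isoelectric point is the
bisection root of that (strictly decreasing) function on [0, 14].
"""

from __future__ import annotations

from dataclasses import dataclass

from .peptide import PeptideRecord
from .residues import (ACIDIC_GROUPS, BASIC_GROUPS, HELIX_PROPENSITY,
                       KYTE_DOOLITTLE, PKA_EMBOSS, canonical_equivalent,
                       is_registered)

__all__ = [
    "CleavageRule", "CleavageHit", "PhysChemProfile", "StabilityThresholds",
    "GateResult", "default_nep_rules", "scan_cleavage", "net_charge",
    "isoelectric_point", "gravy", "helix_propensity", "physchem_profile",
    "stability_gate",
]


@dataclass(frozen=True)
class CleavageRule:
    """A P1-P1' scissile dipeptide, optionally anchored to a template
    position (the template position of the P1 residue)."""

    label: str
    p1_residue: str
    p1prime_residue: str
    p1_template_position: int | None = None

    def __post_init__(self) -> None:
        for tok in (self.p1_residue, self.p1prime_residue):
            if not is_registered(tok):
                raise ValueError(f"rule {self.label!r}: unregistered token "
                                 f"{tok!r}")


@dataclass(frozen=True)
class CleavageHit:
    rule_label: str
    p1_position: int
    dipeptide: tuple[str, str]


@dataclass(frozen=True)
class PhysChemProfile:
    """Per-candidate physicochemical descriptors."""

    net_charge: float
    pI: float | None
    gravy: float
    helix_propensity: float
    length: int
    pH: float = 7.4


@dataclass(frozen=True)
class GateResult:
    """Outcome of a gate: passed iff the reasons list is empty.

    Each reason is ``(criterion, observed, bound)``.
    """

    passed: bool
    reasons: tuple[tuple[str, float | str, float | str], ...] = ()

    def __post_init__(self) -> None:
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must be equivalent to empty reasons")


_INF = float("inf")


@dataclass(frozen=True)
class StabilityThresholds:
    """Bounds for the stability gate.

    Only the cleavage-site cap rejects by default (max 0, the stated
    filter); the physicochemical bounds default to report-only because no
    numeric cutoffs are published for them.
    """

    max_cleavage_sites: int = 0
    net_charge_min: float = -_INF
    net_charge_max: float = _INF
    gravy_max: float = _INF
    helix_propensity_min: float = -_INF
    pi_exclusion: tuple[float, float] | None = None
    pH: float = 7.4

    def __post_init__(self) -> None:
        if self.net_charge_min > self.net_charge_max:
            raise ValueError("net charge range is empty")
        if self.pi_exclusion is not None and \
                self.pi_exclusion[0] > self.pi_exclusion[1]:
            raise ValueError("pI exclusion window is empty")


def default_nep_rules() -> list[CleavageRule]:
    """The six NEP-24.11 scissile dipeptides of GLP-1(7-37), template
    numbered: D15-V16, S18-Y19, Y19-L20, E27-F28, F28-I29, W31-L32."""
    return [
        CleavageRule("Asp15-Val16", "D", "V", 15),
        CleavageRule("Ser18-Tyr19", "S", "Y", 18),
        CleavageRule("Tyr19-Leu20", "Y", "L", 19),
        CleavageRule("Glu27-Phe28", "E", "F", 27),
        CleavageRule("Phe28-Ile29", "F", "I", 28),
        CleavageRule("Trp31-Leu32", "W", "L", 31),
    ]


def scan_cleavage(record: PeptideRecord, rules: list[CleavageRule] | None = None,
                  mode: str = "position_anchored") -> list[CleavageHit]:
    """Find scissile dipeptides in a candidate.

    ``position_anchored`` checks each rule only at its template position
    (the enzyme-mapping convention); ``motif_scan`` reports every adjacent
    residue pair matching a rule's dipeptide anywhere in the sequence,
    which is stricter for designs that relocate motifs.  Hits are sorted by
    position then rule label.
    """
    if rules is None:
        rules = default_nep_rules()
    if mode not in ("position_anchored", "motif_scan"):
        raise ValueError(f"unknown scan mode {mode!r}")
    hits: list[CleavageHit] = []
    positions = record.positions
    if mode == "position_anchored":
        for rule in rules:
            if rule.p1_template_position is None:
                raise ValueError(
                    f"rule {rule.label!r} has no template position; "
                    "use motif_scan"
                )
            p = rule.p1_template_position
            if p in positions and (p + 1) in positions:
                pair = (record.token_at(p), record.token_at(p + 1))
                if pair == (rule.p1_residue, rule.p1prime_residue):
                    hits.append(CleavageHit(rule.label, p, pair))
    else:
        for i in range(len(record) - 1):
            pair = (record.residues[i], record.residues[i + 1])
            for rule in rules:
                if pair == (rule.p1_residue, rule.p1prime_residue):
                    hits.append(
                        CleavageHit(rule.label,
                                    record.numbering_start + i, pair)
                    )
    hits.sort(key=lambda h: (h.p1_position, h.rule_label))
    return hits


def _ionizable_groups(record: PeptideRecord, pka_table: dict[str, float]
                      ) -> tuple[list[float], list[float]]:
    """(basic pKas, acidic pKas) for a free peptide, termini included."""
    basic = [pka_table["nterm"]]
    acidic = [pka_table["cterm"]]
    for tok in record.residues:
        canon = canonical_equivalent(tok)
        if canon in BASIC_GROUPS:
            basic.append(pka_table[canon])
        elif canon in ACIDIC_GROUPS:
            acidic.append(pka_table[canon])
    return basic, acidic


def net_charge(record: PeptideRecord, pH: float = 7.4,
               pka_table: dict[str, float] | None = None) -> float:
    """Henderson–Hasselbalch net charge (elementary charges) at ``pH``.

    Aib and other non-ionizable tokens contribute nothing beyond the
    termini.
    """
    if not 0.0 < pH < 14.0:
        raise ValueError(f"pH {pH} outside (0, 14)")
    table = PKA_EMBOSS if pka_table is None else pka_table
    basic, acidic = _ionizable_groups(record, table)
    pos = sum(1.0 / (1.0 + 10.0 ** (pH - pka)) for pka in basic)
    neg = sum(1.0 / (1.0 + 10.0 ** (pka - pH)) for pka in acidic)
    return pos - neg


def isoelectric_point(record: PeptideRecord,
                      pka_table: dict[str, float] | None = None,
                      tol: float = 1e-4) -> float:
    """pH at which the net charge vanishes, by bisection on [0, 14].

    Requires at least one acidic and one basic group (termini count); the
    charge is strictly decreasing in pH so the root is unique.
    """
    lo, hi = 1e-9, 14.0 - 1e-9
    f_lo = net_charge(record, lo, pka_table)
    f_hi = net_charge(record, hi, pka_table)
    if f_lo <= 0.0 or f_hi >= 0.0:
        raise ValueError(
            f"net charge has no sign change on (0, 14) for {record.id!r}; "
            "pI undefined"
        )
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if net_charge(record, mid, pka_table) > 0.0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _mean_scale(record: PeptideRecord, scale: dict[str, float],
                what: str) -> float:
    total = 0.0
    for tok in record.residues:
        if tok in scale:
            total += scale[tok]
        elif canonical_equivalent(tok) in scale:
            total += scale[canonical_equivalent(tok)]
        else:
            raise KeyError(f"token {tok!r} missing from {what} scale")
    return total / len(record)


def gravy(record: PeptideRecord, scale: dict[str, float] | None = None
          ) -> float:
    """Mean per-residue hydropathy (Kyte–Doolittle by default; Aib maps to
    Ala's value)."""
    return _mean_scale(record, KYTE_DOOLITTLE if scale is None else scale,
                       "hydropathy")


def helix_propensity(record: PeptideRecord,
                     scale: dict[str, float] | None = None) -> float:
    """Mean per-residue helix propensity (negated helix-formation free
    energy by default: Ala = 0 at the top, Gly = -1, Pro lowest)."""
    return _mean_scale(record,
                       HELIX_PROPENSITY if scale is None else scale,
                       "helix propensity")


def physchem_profile(record: PeptideRecord, pH: float = 7.4,
                     pka_table: dict[str, float] | None = None
                     ) -> PhysChemProfile:
    """Assemble the descriptor block for one candidate.

    ``pI`` is None for peptides without both group signs (e.g. a free
    poly-Lys has no acidic side chain beyond the C-terminus, which keeps
    pI defined for most real peptides).
    """
    try:
        pi: float | None = isoelectric_point(record, pka_table)
    except ValueError:
        pi = None
    return PhysChemProfile(
        net_charge=net_charge(record, pH, pka_table),
        pI=pi,
        gravy=gravy(record),
        helix_propensity=helix_propensity(record),
        length=len(record),
        pH=pH,
    )


def stability_gate(record: PeptideRecord,
                   thresholds: StabilityThresholds | None = None,
                   rules: list[CleavageRule] | None = None,
                   scan_mode: str = "position_anchored") -> GateResult:
    """Evaluate one candidate against the stability thresholds.

    The reasons list names every violated bound with the observed value, so
    a failure can be reproduced criterion by criterion.
    """
    thr = StabilityThresholds() if thresholds is None else thresholds
    hits = scan_cleavage(record, rules, scan_mode)
    reasons: list[tuple[str, float | str, float | str]] = []
    if len(hits) > thr.max_cleavage_sites:
        labels = ",".join(h.rule_label for h in hits)
        reasons.append(
            (f"cleavage_sites[{labels}]", float(len(hits)),
             float(thr.max_cleavage_sites))
        )
    profile = physchem_profile(record, thr.pH)
    if profile.net_charge < thr.net_charge_min:
        reasons.append(("net_charge_min", profile.net_charge,
                        thr.net_charge_min))
    if profile.net_charge > thr.net_charge_max:
        reasons.append(("net_charge_max", profile.net_charge,
                        thr.net_charge_max))
    if profile.gravy > thr.gravy_max:
        reasons.append(("gravy_max", profile.gravy, thr.gravy_max))
    if profile.helix_propensity < thr.helix_propensity_min:
        reasons.append(("helix_propensity_min", profile.helix_propensity,
                        thr.helix_propensity_min))
    if thr.pi_exclusion is not None and profile.pI is not None:
        lo, hi = thr.pi_exclusion
        if lo <= profile.pI <= hi:
            reasons.append(("pI_exclusion", profile.pI, f"[{lo},{hi}]"))
    return GateResult(passed=not reasons, reasons=tuple(reasons))
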