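"""Peptide sequence model, FASTA I/O, template numbering and alignment.

Sequences are lists of residue *tokens* rather than plain strings so that
non-canonical residues such as Aib are first-class.  Positions follow the
GLP-1 convention in which the mature peptide spans template positions 7-37:
residue ``i`` of a record sits at template position ``numbering_start + i``.

The module also carries the Semaglutide design template — GLP-1(7-37) with
Aib at position 8 and Arg at position 34 — and the 13 anchored (fixed)
positions used to build the design mask for the screening funnel.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from .residues import is_registered, tokens_match

__all__ = [
    "PeptideRecord", "TemplateSpec", "DesignMask", "Msa",
    "ConservationProfile", "AlignmentResult",
    "read_fasta", "write_fasta", "read_msa", "parse_sequence",
    "format_sequence", "write_conservation_tsv",
    "conservation_profile", "select_conserved_sites", "build_design_mask",
    "recovery", "dedupe", "global_align", "make_substitution",
    "semaglutide_template", "glp1_7_37", "semaglutide_template_spec",
    "SEMAGLUTIDE_ANCHORS", "DEFAULT_NUMBERING_START",
]

DEFAULT_NUMBERING_START = 7

GAP_TOKENS = frozenset({"-", "."})


@dataclass(frozen=True)
class PeptideRecord:
    """An identified peptide with template-relative numbering.

    Parameters
    ----------
    id : str
        Record identifier (FASTA header word).
    residues : tuple of str
        Residue tokens, N to C.
    numbering_start : int
        Template position of the first residue (default 7, the GLP-1
        convention).
    annotations : dict
        Free-form key -> string metadata (e.g. fatty-acid chain notes).
    """

    id: str
    residues: tuple[str, ...]
    numbering_start: int = DEFAULT_NUMBERING_START
    annotations: dict[str, str] = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        object.__setattr__(self, "residues", tuple(self.residues))
        for tok in self.residues:
            if not is_registered(tok):
                raise ValueError(
                    f"record {self.id!r}: unregistered residue token {tok!r}"
                )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def positions(self) -> range:
        """Template positions covered by this record."""
        return range(self.numbering_start, self.numbering_start + len(self))

    def token_at(self, position: int) -> str:
        """Residue token at a template position."""
        i = position - self.numbering_start
        if not 0 <= i < len(self.residues):
            raise KeyError(
                f"position {position} outside record {self.id!r} "
                f"({self.positions.start}-{self.positions.stop - 1})"
            )
        return self.residues[i]

    @property
    def sequence(self) -> str:
        """Bracket-token string form, e.g. ``H[Aib]EGT``."""
        return format_sequence(self.residues)


@dataclass(frozen=True)
class TemplateSpec:
    """Design template plus the anchored (required) positions."""

    template: PeptideRecord
    anchored_positions: frozenset[int]

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "anchored_positions", frozenset(self.anchored_positions)
        )
        rng = self.template.positions
        for p in self.anchored_positions:
            if p not in rng:
                raise ValueError(
                    f"anchored position {p} outside template range "
                    f"{rng.start}-{rng.stop - 1}"
                )

    def anchored_token(self, position: int) -> str:
        if position not in self.anchored_positions:
            raise KeyError(f"{position} is not an anchored position")
        return self.template.token_at(position)


@dataclass(frozen=True)
class DesignMask:
    """Partition of template positions into fixed and designable sets."""

    fixed: frozenset[int]
    designable: frozenset[int]

    def __post_init__(self) -> None:
        if self.fixed & self.designable:
            raise ValueError("fixed and designable positions overlap")


@dataclass(frozen=True)
class Msa:
    """A gapped multiple alignment of residue-token rows."""

    rows: tuple[tuple[str, tuple[str, ...]], ...]

    def __post_init__(self) -> None:
        if not self.rows:
            raise ValueError("empty alignment")
        n = len(self.rows[0][1])
        for rid, seq in self.rows:
            if len(seq) != n:
                raise ValueError(f"row {rid!r} has length {len(seq)} != {n}")
        for j in range(n):
            if all(seq[j] in GAP_TOKENS for _, seq in self.rows):
                raise ValueError(f"column {j} is all gaps")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0][1])

    def column(self, j: int) -> list[str]:
        return [seq[j] for _, seq in self.rows]


@dataclass(frozen=True)
class ConservationProfile:
    """Per-column conservation scores.

    ``mode`` is ``majority_fraction`` (scores in [0, 1]) or
    ``shannon_entropy`` (bits; *low* entropy means conserved).
    """

    scores: tuple[float, ...]
    mode: str


@dataclass(frozen=True)
class AlignmentResult:
    """A pairwise global alignment: gapped rows, DP score and identity."""

    aligned_a: tuple[str, ...]
    aligned_b: tuple[str, ...]
    score: float
    identity: float


# --------------------------------------------------------------------------
# FASTA (bracket-token dialect)

_TOKEN_RE = re.compile(r"\[([A-Za-z0-9]+)\]|(.)")


def parse_sequence(text: str) -> tuple[str, ...]:
    """Parse a bracket-token sequence string into residue tokens.

    ``"H[Aib]EGT"`` -> ``("H", "Aib", "E", "G", "T")``.  Raises
    ``ValueError`` for unregistered tokens.
    """
    tokens: list[str] = []
    for m in _TOKEN_RE.finditer(text.strip()):
        tok = m.group(1) if m.group(1) is not None else m.group(2)
        if tok.isspace():
            continue
        if not is_registered(tok):
            raise ValueError(f"unregistered residue token {tok!r}")
        tokens.append(tok)
    return tuple(tokens)


def format_sequence(tokens: tuple[str, ...] | list[str]) -> str:
    return "".join(t if len(t) == 1 else f"[{t}]" for t in tokens)


def read_fasta(path: str | Path) -> list[PeptideRecord]:
    """Read peptide records from FASTA with bracketed extended tokens.

    The header may carry ``key=value`` annotations after the id; a
    ``start=`` key sets ``numbering_start`` (default 7).
    """
    text = Path(path).read_text()
    records: list[PeptideRecord] = []
    header: str | None = None
    chunks: list[str] = []

    def flush() -> None:
        if header is None:
            return
        if not chunks:
            raise ValueError(f"header {header!r} without sequence")
        fields = header.split()
        rid, extras = fields[0], fields[1:]
        annotations: dict[str, str] = {}
        start = DEFAULT_NUMBERING_START
        for item in extras:
            if "=" in item:
                k, v = item.split("=", 1)
                if k == "start":
                    start = int(v)
                else:
                    annotations[k] = v
        records.append(
            PeptideRecord(rid, parse_sequence("".join(chunks)), start,
                          annotations)
        )

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            flush()
            header = line[1:].strip()
            chunks = []
        else:
            if header is None:
                raise ValueError("sequence data before first FASTA header")
            chunks.append(line)
    flush()
    if not records:
        raise ValueError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[PeptideRecord], path: str | Path,
                width: int = 60) -> None:
    """Write records in the bracket-token FASTA dialect (start= in header)."""
    lines: list[str] = []
    for rec in records:
        header = f">{rec.id} start={rec.numbering_start}"
        for k, v in rec.annotations.items():
            header += f" {k}={v}"
        lines.append(header)
        seq = rec.sequence
        lines.extend(seq[i:i + width] for i in range(0, len(seq), width))
    Path(path).write_text("\n".join(lines) + "\n")


def read_msa(path: str | Path) -> Msa:
    """Read an aligned FASTA file into an :class:`Msa` (gaps ``-``/``.``)."""
    text = Path(path).read_text()
    rows: list[tuple[str, tuple[str, ...]]] = []
    header: str | None = None
    chunks: list[str] = []

    def parse_gapped(s: str) -> tuple[str, ...]:
        out: list[str] = []
        for m in _TOKEN_RE.finditer(s):
            tok = m.group(1) if m.group(1) is not None else m.group(2)
            if tok.isspace():
                continue
            if tok not in GAP_TOKENS and not is_registered(tok):
                raise ValueError(f"unregistered residue token {tok!r}")
            out.append(tok)
        return tuple(out)

    for line in text.splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith(">"):
            if header is not None:
                rows.append((header.split()[0], parse_gapped("".join(chunks))))
            header = line[1:].strip()
            chunks = []
        else:
            chunks.append(line)
    if header is not None:
        rows.append((header.split()[0], parse_gapped("".join(chunks))))
    return Msa(tuple(rows))


# --------------------------------------------------------------------------
# Conservation and design mask

def conservation_profile(msa: Msa, mode: str = "majority_fraction"
                         ) -> ConservationProfile:
    """Per-column conservation of an alignment, gaps excluded from counts.

    ``majority_fraction``: frequency of the most common residue in the
    column.  ``shannon_entropy``: Shannon entropy in bits over the column's
    residue distribution (0 for unanimous columns).
    """
    if mode not in ("majority_fraction", "shannon_entropy"):
        raise ValueError(f"unknown conservation mode {mode!r}")
    scores: list[float] = []
    for j in range(msa.n_columns):
        col = [t for t in msa.column(j) if t not in GAP_TOKENS]
        counts: dict[str, int] = {}
        for t in col:
            counts[t] = counts.get(t, 0) + 1
        total = len(col)
        if mode == "majority_fraction":
            scores.append(max(counts.values()) / total)
        else:
            ent = -sum((c / total) * math.log2(c / total)
                       for c in counts.values())
            scores.append(ent)
    return ConservationProfile(tuple(scores), mode)


def select_conserved_sites(profile: ConservationProfile, threshold: float,
                           anchors: frozenset[int] | set[int],
                           template: PeptideRecord | None = None,
                           column_positions: list[int] | None = None,
                           ) -> frozenset[int]:
    """Template positions whose conservation meets ``threshold``, plus anchors.

    ``column_positions`` maps alignment columns to template positions; if
    omitted, column ``j`` maps to ``start + j`` where ``start`` comes from
    ``template`` (or the default GLP-1 numbering).  In entropy mode a column
    is conserved when its entropy is *at most* ``threshold``.
    """
    start = (template.numbering_start if template is not None
             else DEFAULT_NUMBERING_START)
    if column_positions is None:
        column_positions = [start + j for j in range(len(profile.scores))]
    if template is not None:
        rng = template.positions
        for a in anchors:
            if a not in rng:
                raise ValueError(f"anchor {a} outside template range")
    picked: set[int] = set(anchors)
    for j, s in enumerate(profile.scores):
        hit = (s <= threshold if profile.mode == "shannon_entropy"
               else s >= threshold)
        if hit:
            picked.add(column_positions[j])
    return frozenset(picked)


def write_conservation_tsv(profile: ConservationProfile, path: str | Path,
                           column_positions: list[int] | None = None
                           ) -> None:
    """Export a conservation profile as TSV (position, score, mode)."""
    if column_positions is None:
        column_positions = [DEFAULT_NUMBERING_START + j
                            for j in range(len(profile.scores))]
    lines = ["position\tscore\tmode"]
    lines += [f"{p}\t{s:.6f}\t{profile.mode}"
              for p, s in zip(column_positions, profile.scores)]
    Path(path).write_text("\n".join(lines) + "\n")


def build_design_mask(template_spec: TemplateSpec) -> DesignMask:
    """Fixed = anchored positions; designable = everything else."""
    all_positions = frozenset(template_spec.template.positions)
    fixed = frozenset(template_spec.anchored_positions)
    return DesignMask(fixed=fixed, designable=all_positions - fixed)


# --------------------------------------------------------------------------
# Recovery and deduplication

def _round_half_up(x: float, ndigits: int) -> float:
    factor = 10 ** ndigits
    return math.floor(x * factor + 0.5) / factor


def recovery(candidate: PeptideRecord, template: PeptideRecord,
             ndigits: int | None = 2) -> float:
    """Fraction of template positions where the candidate matches.

    The denominator is the template length; tokens match under the
    extended-token equivalence (Aib matches Ala and Aib).  Values are
    reported rounded half-up to ``ndigits`` decimals (pass ``None`` for the
    raw fraction).
    """
    if (candidate.numbering_start != template.numbering_start
            or len(candidate) != len(template)):
        raise ValueError(
            f"numbering mismatch: candidate {candidate.positions} vs "
            f"template {template.positions}"
        )
    matches = sum(
        tokens_match(a, b)
        for a, b in zip(candidate.residues, template.residues)
    )
    frac = matches / len(template)
    return frac if ndigits is None else _round_half_up(frac, ndigits)


def dedupe(records: list[PeptideRecord]
           ) -> tuple[list[PeptideRecord], dict[str, int]]:
    """Keep the first occurrence of each distinct token sequence.

    Returns the unique records (input order preserved) and a summary with
    ``n_in``, ``n_unique`` and ``n_duplicates``.
    """
    seen: set[tuple[str, ...]] = set()
    unique: list[PeptideRecord] = []
    for rec in records:
        if rec.residues not in seen:
            seen.add(rec.residues)
            unique.append(rec)
    return unique, {
        "n_in": len(records),
        "n_unique": len(unique),
        "n_duplicates": len(records) - len(unique),
    }


# --------------------------------------------------------------------------
# Pairwise global alignment (Needleman-Wunsch, linear gaps)

def make_substitution(match: float = 1.0, mismatch: float = 0.0):
    """Token-pair score function scoring ``match`` for equivalent tokens
    (under the Aib/Ala policy) and ``mismatch`` otherwise."""
    def score(a: str, b: str) -> float:
        return match if tokens_match(a, b) else mismatch
    return score


def global_align(a: PeptideRecord | tuple[str, ...], b: PeptideRecord | tuple[str, ...],
                 substitution=None, gap_penalty: float = 1.0
                 ) -> AlignmentResult:
    """Optimal global alignment with linear gap penalty.

    ``substitution`` is a symmetric callable ``(token, token) -> score``
    (default: match 1 / mismatch 0 under the token-equivalence policy);
    ``gap_penalty`` is subtracted per gap column.  Traceback ties break
    deterministically: diagonal, then up (gap in b), then left (gap in a).
    Identity is identical aligned columns over alignment length.
    """
    sa = a.residues if isinstance(a, PeptideRecord) else tuple(a)
    sb = b.residues if isinstance(b, PeptideRecord) else tuple(b)
    if substitution is None:
        substitution = make_substitution()
    g = float(gap_penalty)
    n, m = len(sa), len(sb)

    score = [[0.0] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        score[i][0] = -g * i
    for j in range(1, m + 1):
        score[0][j] = -g * j
    for i in range(1, n + 1):
        row, prev = score[i], score[i - 1]
        ai = sa[i - 1]
        for j in range(1, m + 1):
            row[j] = max(prev[j - 1] + substitution(ai, sb[j - 1]),
                         prev[j] - g, row[j - 1] - g)

    # Traceback with the fixed tie-break order.
    out_a: list[str] = []
    out_b: list[str] = []
    i, j = n, m
    while i > 0 or j > 0:
        if i > 0 and j > 0 and math.isclose(
                score[i][j],
                score[i - 1][j - 1] + substitution(sa[i - 1], sb[j - 1])):
            out_a.append(sa[i - 1]); out_b.append(sb[j - 1])
            i -= 1; j -= 1
        elif i > 0 and math.isclose(score[i][j], score[i - 1][j] - g):
            out_a.append(sa[i - 1]); out_b.append("-")
            i -= 1
        else:
            out_a.append("-"); out_b.append(sb[j - 1])
            j -= 1
    out_a.reverse(); out_b.reverse()
    length = len(out_a)
    ident = sum(
        1 for x, y in zip(out_a, out_b)
        if x != "-" and y != "-" and tokens_match(x, y)
    ) / length if length else 1.0
    return AlignmentResult(tuple(out_a), tuple(out_b), score[n][m], ident)


# --------------------------------------------------------------------------
# The GLP-1 / Semaglutide design template

_GLP1_7_37 = "HAEGTFTSDVSSYLEGQAAKEFIAWLVKGRG"

#: Anchored template positions: the 13 fixed residue points
#: 7H 8Aib 9E 10G 11T 12F 13T 14S 15D 17S 26K 34R 37G.
SEMAGLUTIDE_ANCHORS = frozenset(
    {7, 8, 9, 10, 11, 12, 13, 14, 15, 17, 26, 34, 37}
)


def glp1_7_37() -> PeptideRecord:
    """Canonical GLP-1(7-37), 31 residues, numbered 7-37."""
    return PeptideRecord("GLP-1_7-37", tuple(_GLP1_7_37), 7)


def semaglutide_template() -> PeptideRecord:
    """The Semaglutide peptide backbone: GLP-1(7-37) with Aib8 and Arg34.

    The fatty-acid conjugation at Lys26 is metadata, not a residue token.
    """
    residues = list(_GLP1_7_37)
    residues[8 - 7] = "Aib"
    residues[34 - 7] = "R"
    return PeptideRecord(
        "Semaglutide", tuple(residues), 7,
        {"conjugation": "C18-diacid@K26"},
    )


def semaglutide_template_spec() -> TemplateSpec:
    """Semaglutide template with its 13 anchored positions."""
    return TemplateSpec(semaglutide_template(), SEMAGLUTIDE_ANCHORS)
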