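"""Residue token registry and physicochemical scale tables.

Residue tokens are the unit of sequence in this package: the 20 canonical
one-letter codes plus registered extended tokens for non-canonical residues.
The only extended token shipped by default is ``Aib`` (2-aminoisobutyric
acid), the helix-stabilising, protease-resistant residue found at position 8
of Semaglutide.  Extended tokens are serialized in brackets in FASTA
(``H[Aib]EGT...``).

All scales are plain dicts keyed by token so they can be overridden or
extended from configuration.  Scale provenance:

* ``KYTE_DOOLITTLE`` — the classic GRAVY hydropathy scale.
* ``HELIX_PROPENSITY`` — negated helix-formation free energies
  (kcal/mol, Ala = 0 at the top, Pro strongly negative); higher means more
  helix-favourable, so a *minimum* threshold is natural.
* ``PKA_EMBOSS`` — EMBOSS-style ionizable-group pKa values used for net
  charge and isoelectric point.
* ``SAP_HYDROPHOBICITY`` — Black–Mould-style hydrophobicity normalized to
  [0, 1] and shifted so Gly = 0, the convention used by spatial
  aggregation propensity scoring (hydrophilic residues go negative).
* ``MAX_SIDECHAIN_SASA`` — fully exposed side-chain solvent-accessible
  areas (Å²) in a Gly-X-Gly context, the denominator of SAP exposure
  fractions.
* ``VDW_RADII`` — element van der Waals radii (Å) for SASA.
"""

from __future__ import annotations

CANONICAL_AA: tuple[str, ...] = tuple("ACDEFGHIKLMNPQRSTVWY")

#: Extended (non-canonical) tokens and the canonical residue each one is
#: treated as when a scale or matching policy needs a canonical stand-in.
EXTENDED_TOKENS: dict[str, str] = {"Aib": "A"}

THREE_LETTER: dict[str, str] = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
    "Aib": "AIB",
}
ONE_LETTER: dict[str, str] = {v: k for k, v in THREE_LETTER.items()}


def is_registered(token: str) -> bool:
    """True if ``token`` is a canonical one-letter code or a registered
    extended token."""
    return token in CANONICAL_AA or token in EXTENDED_TOKENS


def canonical_equivalent(token: str) -> str:
    """Canonical one-letter stand-in for a token (identity for canonical)."""
    if token in EXTENDED_TOKENS:
        return EXTENDED_TOKENS[token]
    if token in CANONICAL_AA:
        return token
    raise KeyError(f"unregistered residue token {token!r}")


def tokens_match(a: str, b: str) -> bool:
    """Equivalence policy for recovery/identity counting.

    Two tokens match if they are equal, or if either is an extended token
    whose canonical stand-in equals the other (so Aib matches both Aib and
    Ala).  Designed sequences are emitted with canonical residues while the
    template carries Aib; the biosynthesized constructs likewise replace
    Aib by Ala, yet are scored against the Aib-containing template.
    """
    if a == b:
        return True
    try:
        return canonical_equivalent(a) == canonical_equivalent(b)
    except KeyError:
        return False


KYTE_DOOLITTLE: dict[str, float] = {
    "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
    "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
    "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
    "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    "Aib": 1.8,  # mapped to Ala
}

# Helix-formation free energies, kcal/mol relative to Ala; negated so that
# larger = more helix-favourable.
_HELIX_DDG: dict[str, float] = {
    "A": 0.00, "L": 0.21, "R": 0.21, "M": 0.24, "K": 0.26,
    "Q": 0.39, "E": 0.40, "I": 0.41, "W": 0.49, "S": 0.50,
    "Y": 0.53, "F": 0.54, "H": 0.61, "V": 0.61, "N": 0.65,
    "T": 0.66, "C": 0.68, "D": 0.69, "G": 1.00, "P": 3.16,
}
HELIX_PROPENSITY: dict[str, float] = {k: -v for k, v in _HELIX_DDG.items()}
HELIX_PROPENSITY["Aib"] = HELIX_PROPENSITY["A"]

#: EMBOSS-style pKa values.  ``nterm``/``cterm`` are the free termini;
#: side-chain keys are canonical tokens.  Sign: K, R, H and the N-terminus
#: are basic; D, E, C, Y and the C-terminus are acidic.
PKA_EMBOSS: dict[str, float] = {
    "nterm": 8.6, "cterm": 3.6,
    "K": 10.8, "R": 12.5, "H": 6.5,
    "D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1,
}
BASIC_GROUPS = frozenset({"K", "R", "H"})
ACIDIC_GROUPS = frozenset({"D", "E", "C", "Y"})

# Black-Mould-style normalized hydrophobicity, shifted so Gly = 0.
_BLACK_MOULD: dict[str, float] = {
    "A": 0.616, "C": 0.680, "D": 0.028, "E": 0.043, "F": 1.000,
    "G": 0.501, "H": 0.165, "I": 0.943, "K": 0.283, "L": 0.943,
    "M": 0.738, "N": 0.236, "P": 0.711, "Q": 0.251, "R": 0.000,
    "S": 0.359, "T": 0.450, "V": 0.825, "W": 0.878, "Y": 0.880,
}
SAP_HYDROPHOBICITY: dict[str, float] = {
    k: round(v - _BLACK_MOULD["G"], 3) for k, v in _BLACK_MOULD.items()
}
SAP_HYDROPHOBICITY["Aib"] = SAP_HYDROPHOBICITY["A"]

# Fully exposed side-chain SASA, Gly-X-Gly context (Å²).  Gly has no
# side-chain heavy atoms; its entry is a guard value that is never used as
# a denominator because no side-chain atom carries the GLY type.
MAX_SIDECHAIN_SASA: dict[str, float] = {
    "A": 67.0, "R": 196.0, "N": 113.0, "D": 106.0, "C": 104.0,
    "E": 138.0, "Q": 144.0, "G": 1.0, "H": 151.0, "I": 140.0,
    "L": 137.0, "K": 167.0, "M": 160.0, "F": 175.0, "P": 105.0,
    "S": 80.0, "T": 102.0, "W": 217.0, "Y": 187.0, "V": 117.0,
    "Aib": 67.0,
}

VDW_RADII: dict[str, float] = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
}
VDW_FALLBACK = 1.8

#: Backbone atom names; everything else in a residue is side chain.
BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "HA"})
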