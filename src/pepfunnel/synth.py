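"""Synthetic inputs for exercising every stage of the screening funnel.

Real campaign inputs (deep-learning sequence designs, predicted complex
structures, confidence files) come from external tools; this module
generates stand-ins with controllable properties so the whole pipeline is
testable without downloads:

* template-constrained candidate sequences — point substitutions at the
  designable positions with a configurable token distribution, an exact
  duplicate fraction, and optional cleavage-site spiking;
* ideal α-helical backbones built by sequential internal-coordinate (NeRF)
  construction with canonical stereochemistry, plus Gaussian coordinate
  perturbation for RMSD/TM test pairs;
* mock confidence data (per-residue pLDDT, PAE matrices) with separable
  intra-/inter-chain error levels.

The sequence generator does not attempt to mimic a learned design
distribution: a position-independent substitution model is enough to
exercise every gate, and conclusions from it transfer to real designs only
at the level of pipeline mechanics, not of biology.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass

import numpy as np

from .peptide import DesignMask, PeptideRecord, TemplateSpec, build_design_mask
from .residues import CANONICAL_AA, THREE_LETTER, is_registered
from .stability import CleavageRule, default_nep_rules
from .structure import AtomRecord, PAEMatrix, StructureModel, _build_index

__all__ = [
    "GeneratorSpec", "HelixParams", "MOTIF_FREE_ALPHABET",
    "generate_candidates", "spike_cleavage_sites", "build_ideal_helix",
    "perturb_structure", "mock_confidence",
]

#: Alphabet free of every NEP-24.11 P1' residue (V, Y, L, F, I), so that
#: sequences drawn from it can never form a scissile dipeptide.
MOTIF_FREE_ALPHABET: tuple[str, ...] = tuple("ACDEGHKMNPQRSTW")


@dataclass(frozen=True)
class GeneratorSpec:
    """Parameters of a synthetic candidate campaign.

    ``distribution`` maps tokens to sampling weights for the designable
    positions (uniform over the 20 canonical residues when None);
    ``duplicate_fraction`` of the ``n`` records are exact resamples of
    earlier outputs; ``cleavage_spike_count`` candidates get one scissile
    dipeptide installed.  Everything is reproducible from ``seed``.
    """

    template_spec: TemplateSpec
    n: int
    distribution: dict[str, float] | None = None
    duplicate_fraction: float = 0.0
    cleavage_spike_count: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n <= 0:
            raise ValueError("n must be positive")
        if not 0.0 <= self.duplicate_fraction < 1.0:
            raise ValueError("duplicate fraction must be in [0, 1)")
        if self.distribution is not None:
            for tok in self.distribution:
                if not is_registered(tok):
                    raise ValueError(
                        f"distribution assigns mass to unregistered token "
                        f"{tok!r}"
                    )


def generate_candidates(spec: GeneratorSpec) -> list[PeptideRecord]:
    """Sample template-constrained candidates.

    Fixed positions always carry the template residue; designable positions
    are drawn i.i.d. from the distribution.  Duplicates are realized by
    resampling earlier outputs under fresh ids.
    """
    rng = np.random.default_rng(spec.seed)
    template = spec.template_spec.template
    mask: DesignMask = build_design_mask(spec.template_spec)
    if spec.distribution is None:
        tokens = list(CANONICAL_AA)
        probs = np.full(len(tokens), 1.0 / len(tokens))
    else:
        tokens = sorted(spec.distribution)
        w = np.array([spec.distribution[t] for t in tokens], dtype=float)
        probs = w / w.sum()

    n_dup = int(math.floor(spec.duplicate_fraction * spec.n))
    n_fresh = spec.n - n_dup
    start = template.numbering_start
    fresh: list[tuple[str, ...]] = []
    for _ in range(n_fresh):
        residues = list(template.residues)
        for pos in sorted(mask.designable):
            residues[pos - start] = tokens[rng.choice(len(tokens), p=probs)]
        fresh.append(tuple(residues))
    sequences = list(fresh)
    for _ in range(n_dup):
        sequences.append(fresh[rng.integers(0, n_fresh)])

    records = [
        PeptideRecord(f"C{i + 1:05d}", seq, start)
        for i, seq in enumerate(sequences)
    ]
    if spec.cleavage_spike_count:
        if spec.cleavage_spike_count > len(records):
            raise ValueError("more spikes requested than candidates")
        which = rng.choice(len(records), size=spec.cleavage_spike_count,
                           replace=False)
        rules = default_nep_rules()
        for idx in sorted(which):
            records[idx] = spike_cleavage_sites(
                records[idx], rules, count=1,
                seed=int(rng.integers(0, 2 ** 31)),
                fixed=mask.fixed,
                template=template,
            )
    return records


def spike_cleavage_sites(record: PeptideRecord,
                         rules: list[CleavageRule] | None = None,
                         count: int = 1, seed: int = 0,
                         fixed: frozenset[int] = frozenset(),
                         template: PeptideRecord | None = None
                         ) -> PeptideRecord:
    """Install ``count`` scissile dipeptides at their template positions.

    A rule is usable if writing its P1/P1' residues does not contradict a
    fixed position (writing the residue the template already fixes there is
    allowed).  Raises when fewer than ``count`` rules are usable.
    """
    if rules is None:
        rules = default_nep_rules()
    rng = np.random.default_rng(seed)
    positions = record.positions

    def usable(rule: CleavageRule) -> bool:
        p = rule.p1_template_position
        if p is None or p not in positions or (p + 1) not in positions:
            return False
        for pos, tok in ((p, rule.p1_residue), (p + 1, rule.p1prime_residue)):
            if pos in fixed:
                ref = (template or record).token_at(pos)
                if ref != tok:
                    return False
        return True

    candidates = [r for r in rules if usable(r)]
    if count > len(candidates):
        raise ValueError(
            f"requested {count} spikes but only {len(candidates)} rules are "
            "compatible with the fixed positions"
        )
    chosen_idx = rng.choice(len(candidates), size=count, replace=False)
    residues = list(record.residues)
    start = record.numbering_start
    for i in sorted(chosen_idx):
        rule = candidates[i]
        p = rule.p1_template_position
        residues[p - start] = rule.p1_residue
        residues[p + 1 - start] = rule.p1prime_residue
    return PeptideRecord(record.id, tuple(residues), start,
                         dict(record.annotations))


# --------------------------------------------------------------------------
# Ideal helix construction

@dataclass(frozen=True)
class HelixParams:
    """Canonical α-helix internal coordinates (degrees, Å)."""

    phi: float = -57.0
    psi: float = -47.0
    omega: float = 180.0
    bond_n_ca: float = 1.458
    bond_ca_c: float = 1.525
    bond_c_n: float = 1.329
    bond_c_o: float = 1.231
    bond_ca_cb: float = 1.521
    angle_n_ca_c: float = 111.2
    angle_ca_c_n: float = 116.2
    angle_c_n_ca: float = 121.7
    angle_ca_c_o: float = 120.5
    angle_n_ca_cb: float = 110.5
    dihedral_c_n_ca_cb: float = -122.6  # L-chirality

    def __post_init__(self) -> None:
        for name in ("phi", "psi", "omega"):
            v = getattr(self, name)
            if not -180.0 < v <= 180.0:
                raise ValueError(f"{name}={v} outside (-180, 180]")


def _nerf(a: np.ndarray, b: np.ndarray, c: np.ndarray,
          bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom D from A-B-C internal coordinates (natural extension
    reference frame)."""
    ang = math.radians(angle_deg)
    tor = math.radians(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(tor),
        bond * math.sin(ang) * math.sin(tor),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def build_ideal_helix(record: PeptideRecord,
                      params: HelixParams | None = None,
                      chain_id: str = "A", origin=(0.0, 0.0, 0.0),
                      start_serial: int = 1) -> StructureModel:
    """Backbone (N, Cα, C, O) plus Cβ for non-Gly residues at ideal helix
    geometry; pLDDT initialized to 100."""
    p = params or HelixParams()
    origin = np.asarray(origin, dtype=float)
    n_res = len(record)

    # seed the first residue in a local frame
    n0 = origin
    ca0 = origin + np.array([p.bond_n_ca, 0.0, 0.0])
    ang = math.radians(p.angle_n_ca_c)
    c0 = ca0 + p.bond_ca_c * np.array([-math.cos(ang), math.sin(ang), 0.0])

    backbone: list[dict[str, np.ndarray]] = [{"N": n0, "CA": ca0, "C": c0}]
    for _ in range(1, n_res):
        prev = backbone[-1]
        n_next = _nerf(prev["N"], prev["CA"], prev["C"],
                       p.bond_c_n, p.angle_ca_c_n, p.psi)
        ca_next = _nerf(prev["CA"], prev["C"], n_next,
                        p.bond_n_ca, p.angle_c_n_ca, p.omega)
        c_next = _nerf(prev["C"], n_next, ca_next,
                       p.bond_ca_c, p.angle_n_ca_c, p.phi)
        backbone.append({"N": n_next, "CA": ca_next, "C": c_next})

    model = StructureModel()
    serial = start_serial
    for i, (tok, atoms) in enumerate(zip(record.residues, backbone)):
        res_name = THREE_LETTER.get(tok, "UNK")
        res_number = record.numbering_start + i
        # carbonyl O: anti to the next N (psi + 180 about N-CA-C)
        o = _nerf(atoms["N"], atoms["CA"], atoms["C"],
                  p.bond_c_o, p.angle_ca_c_o, p.psi + 180.0)
        placed = [("N", atoms["N"], "N"), ("CA", atoms["CA"], "C"),
                  ("C", atoms["C"], "C"), ("O", o, "O")]
        if tok != "G":
            cb = _nerf(atoms["C"], atoms["N"], atoms["CA"],
                       p.bond_ca_cb, p.angle_n_ca_cb, p.dihedral_c_n_ca_cb)
            placed.append(("CB", cb, "C"))
        for name, xyz, element in placed:
            model.add_atom(AtomRecord(
                serial=serial, name=name, res_name=res_name,
                chain_id=chain_id, res_number=res_number,
                xyz=np.round(xyz, 3), bfactor=100.0, element=element,
            ))
            serial += 1
    return model


def perturb_structure(model: StructureModel, sigma: float, seed: int = 0
                      ) -> StructureModel:
    """Isotropic Gaussian displacement of every atom (σ in Å, seeded);
    σ = 0 returns an identical copy."""
    if sigma < 0:
        raise ValueError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    out = copy.deepcopy(model)
    for atom in out.iter_atoms():
        if sigma > 0:
            atom.xyz = atom.xyz + rng.normal(0.0, sigma, size=3)
    return out


def combine_models(*models: StructureModel) -> StructureModel:
    """Merge models with distinct chain ids into one complex."""
    out = StructureModel()
    for m in models:
        for atom in m.iter_atoms():
            out.add_atom(copy.deepcopy(atom))
    return out


def mock_confidence(model_lengths: dict[str, int],
                    plddt_levels: dict[str, float],
                    pae_levels: dict[str, float],
                    seed: int = 0, noise_sd: float = 0.0
                    ) -> tuple[dict[str, np.ndarray], PAEMatrix]:
    """Synthetic per-residue pLDDT and a PAE matrix for a complex.

    ``pae_levels`` carries ``intra`` and ``inter`` mean error levels (Å);
    pLDDT values are drawn around the per-chain means and clipped to
    [0, 100].  With ``noise_sd = 0`` the outputs equal the requested
    levels exactly.
    """
    for key in ("intra", "inter"):
        if pae_levels[key] < 0:
            raise ValueError(f"{key} pAE level must be nonnegative")
    rng = np.random.default_rng(seed)
    plddt: dict[str, np.ndarray] = {}
    for chain, length in model_lengths.items():
        vals = np.full(length, float(plddt_levels[chain]))
        if noise_sd > 0:
            vals = vals + rng.normal(0.0, noise_sd, size=length)
        plddt[chain] = np.clip(vals, 0.0, 100.0)

    index = _build_index(model_lengths)
    n = len(index)
    chain_of = np.array([c for c, _ in index])
    inter = chain_of[:, None] != chain_of[None, :]
    matrix = np.where(inter, pae_levels["inter"], pae_levels["intra"])
    matrix = matrix.astype(float)
    if noise_sd > 0:
        matrix = matrix + rng.normal(0.0, noise_sd, size=(n, n))
    np.fill_diagonal(matrix, 0.0)
    matrix = np.clip(matrix, 0.0, None)
    return plddt, PAEMatrix(matrix, index)
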