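"""Efficacy-gate structural metrics for predicted peptide-receptor complexes.

Covers the metrics used to judge whether a designed agonist folds and binds
like the native reference complex:

* Kabsch least-squares superposition and Cα RMSD;
* TM-score with the standard length-dependent distance scale
  ``d0 = 1.24 (L-15)^(1/3) - 1.8`` (clamped below at 0.5 Å) and iterative
  Kabsch reweighting on the sub-d0 pairs;
* Shrake–Rupley solvent-accessible surface area with a deterministic
  golden-spiral sphere point set (bit-reproducible, no RNG);
* spatial aggregation propensity (SAP): per residue, the sum over nearby
  side-chain atoms of exposure fraction times residue hydrophobicity;
* mean pLDDT (read from the B-factor column, the structure-predictor
  convention) and interface pAE (mean over inter-chain blocks of the
  predicted-aligned-error matrix);
* threshold derivation from the reference complex and the efficacy gate
  itself; external binding-affinity scores are ingested, never computed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .residues import (MAX_SIDECHAIN_SASA, ONE_LETTER, SAP_HYDROPHOBICITY,
                       BACKBONE_ATOMS, VDW_FALLBACK, VDW_RADII)
from .stability import GateResult

__all__ = [
    "AtomRecord", "Residue", "Chain", "StructureModel", "PAEMatrix",
    "read_pdb", "write_pdb", "read_pae_json", "write_pae_json",
    "kabsch", "ca_rmsd", "tm_score", "tm_d0", "shrake_rupley",
    "SapParams", "sap", "mean_plddt", "interface_pae",
    "StructScore", "EfficacyThresholds", "derive_thresholds",
    "efficacy_gate", "ingest_affinity",
]


@dataclass
class AtomRecord:
    serial: int
    name: str
    res_name: str
    chain_id: str
    res_number: int
    xyz: np.ndarray
    bfactor: float = 0.0
    element: str = ""

    def __post_init__(self) -> None:
        self.xyz = np.asarray(self.xyz, dtype=float)
        if self.xyz.shape != (3,) or not np.all(np.isfinite(self.xyz)):
            raise ValueError(f"atom {self.serial}: bad coordinates")
        if not self.name:
            raise ValueError(f"atom {self.serial}: empty atom name")
        if not self.element:
            self.element = self.name.lstrip("0123456789")[:1].upper()


@dataclass
class Residue:
    name: str
    number: int
    atoms: list[AtomRecord] = field(default_factory=list)
    plddt: float | None = None

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None


@dataclass
class Chain:
    id: str
    residues: dict[int, Residue] = field(default_factory=dict)


@dataclass
class StructureModel:
    """Atoms grouped chain -> residue -> atom, with per-residue pLDDT."""

    chains: dict[str, Chain] = field(default_factory=dict)

    def add_atom(self, atom: AtomRecord) -> None:
        chain = self.chains.setdefault(atom.chain_id, Chain(atom.chain_id))
        res = chain.residues.get(atom.res_number)
        if res is None:
            res = Residue(atom.res_name, atom.res_number)
            chain.residues[atom.res_number] = res
        res.atoms.append(atom)
        if atom.name == "CA":
            res.plddt = atom.bfactor

    def iter_atoms(self):
        for chain in self.chains.values():
            for res in chain.residues.values():
                yield from res.atoms

    def iter_residues(self):
        for chain in self.chains.values():
            yield from chain.residues.values()

    def ca_coords(self, chain_id: str) -> dict[int, np.ndarray]:
        """Residue number -> Cα coordinate for one chain."""
        chain = self.chains[chain_id]
        out: dict[int, np.ndarray] = {}
        for num, res in chain.residues.items():
            ca = res.atom("CA")
            if ca is not None:
                out[num] = ca.xyz
        return out


# --------------------------------------------------------------------------
# PDB I/O (fixed-column ATOM/HETATM records only)

def read_pdb(path: str | Path) -> StructureModel:
    """Parse ATOM/HETATM records; altloc blank or 'A' kept, others dropped.

    The Cα B-factor is stored as the residue's pLDDT (the structure-
    predictor convention).
    """
    model = StructureModel()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        if len(line) < 54:
            raise ValueError(
                f"{path}:{lineno}: ATOM record shorter than coordinate "
                "columns"
            )
        altloc = line[16]
        if altloc not in (" ", "A"):
            continue
        try:
            atom = AtomRecord(
                serial=int(line[6:11]),
                name=line[12:16].strip(),
                res_name=line[17:20].strip(),
                chain_id=line[21].strip() or "A",
                res_number=int(line[22:26]),
                xyz=np.array([float(line[30:38]), float(line[38:46]),
                              float(line[46:54])]),
                bfactor=float(line[60:66]) if len(line) >= 66 else 0.0,
                element=line[76:78].strip() if len(line) >= 78 else "",
            )
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: malformed ATOM record "
                             f"({exc})") from exc
        model.add_atom(atom)
    if not model.chains:
        raise ValueError(f"{path}: no ATOM/HETATM records")
    return model


def write_pdb(model: StructureModel, path: str | Path) -> None:
    """Minimal fixed-column writer (fixtures and interchange)."""
    lines: list[str] = []
    for chain in model.chains.values():
        for res in chain.residues.values():
            for a in res.atoms:
                name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
                lines.append(
                    f"ATOM  {a.serial:>5d} {name:<4s} {a.res_name:<3s} "
                    f"{chain.id}{res.number:>4d}    "
                    f"{a.xyz[0]:8.3f}{a.xyz[1]:8.3f}{a.xyz[2]:8.3f}"
                    f"{1.00:6.2f}{a.bfactor:6.2f}          "
                    f"{a.element:>2s}"
                )
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# Predicted aligned error

@dataclass
class PAEMatrix:
    """Square predicted-aligned-error matrix with a residue index map."""

    matrix: np.ndarray
    index: tuple[tuple[str, int], ...]  # row i -> (chain id, residue number)

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n, m = self.matrix.shape
        if n != m:
            raise ValueError(f"PAE matrix is {n}x{m}, not square")
        if len(self.index) != n:
            raise ValueError("index map length does not match matrix")
        if np.any(self.matrix < 0):
            raise ValueError("PAE entries must be nonnegative")

    def chain_rows(self, chain_id: str) -> np.ndarray:
        rows = np.array([i for i, (c, _) in enumerate(self.index)
                         if c == chain_id], dtype=int)
        if rows.size == 0:
            raise KeyError(f"chain {chain_id!r} not in PAE index")
        return rows


def _build_index(chain_lengths: dict[str, int] | list[tuple[str, int]]
                 ) -> tuple[tuple[str, int], ...]:
    items = (list(chain_lengths.items())
             if isinstance(chain_lengths, dict) else list(chain_lengths))
    index: list[tuple[str, int]] = []
    for chain_id, length in items:
        index.extend((chain_id, i + 1) for i in range(length))
    return tuple(index)


def read_pae_json(path: str | Path,
                  chain_lengths: dict[str, int] | list[tuple[str, int]]
                  ) -> PAEMatrix:
    """Read a predicted-aligned-error JSON file.

    Both common dialects are accepted: a bare object with a
    ``predicted_aligned_error`` (or ``pae``) key, and the list-wrapped form
    ``[{...}]``.  ``chain_lengths`` supplies the residue index map.
    """
    data = json.loads(Path(path).read_text())
    if isinstance(data, list):
        if not data:
            raise ValueError(f"{path}: empty PAE JSON list")
        data = data[0]
    matrix = None
    for key in ("predicted_aligned_error", "pae"):
        if key in data:
            matrix = np.asarray(data[key], dtype=float)
            break
    if matrix is None:
        raise ValueError(f"{path}: no predicted-aligned-error key found")
    return PAEMatrix(matrix, _build_index(chain_lengths))


def write_pae_json(pae: PAEMatrix, path: str | Path) -> None:
    payload = {"predicted_aligned_error": pae.matrix.tolist(),
               "max_predicted_aligned_error": float(pae.matrix.max())}
    Path(path).write_text(json.dumps(payload))


# --------------------------------------------------------------------------
# Superposition and similarity scores

def kabsch(coords_a: np.ndarray, coords_b: np.ndarray
           ) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares superposition of ``coords_b`` onto ``coords_a``.

    Returns ``(rotation, translation, rmsd)`` with
    ``coords_a ≈ coords_b @ rotation.T + translation``.  The rotation is
    proper (det +1, reflections corrected).  Degenerate (collinear) point
    sets are tolerated; n < 3 raises.
    """
    a = np.asarray(coords_a, dtype=float)
    b = np.asarray(coords_b, dtype=float)
    if a.shape != b.shape or a.ndim != 2 or a.shape[1] != 3:
        raise ValueError("point lists must both be n x 3")
    n = a.shape[0]
    if n < 3:
        raise ValueError("need at least 3 points for superposition")
    ca, cb = a.mean(axis=0), b.mean(axis=0)
    h = (b - cb).T @ (a - ca)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    r = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = ca - r @ cb
    diff = a - (b @ r.T + t)
    rmsd = float(np.sqrt((diff ** 2).sum() / n))
    return r, t, rmsd


def _paired_ca(model: StructureModel, reference: StructureModel,
               chain: str, positions=None
               ) -> tuple[np.ndarray, np.ndarray]:
    ca_m = model.ca_coords(chain)
    ca_r = reference.ca_coords(chain)
    common = sorted(set(ca_m) & set(ca_r))
    if positions is not None:
        common = [p for p in common if p in set(positions)]
        missing = set(positions) - set(common)
        if missing:
            raise ValueError(f"missing Cα for paired positions {sorted(missing)}")
    if len(common) < 3:
        raise ValueError("fewer than 3 paired Cα positions")
    return (np.array([ca_m[p] for p in common]),
            np.array([ca_r[p] for p in common]))


def ca_rmsd(model: StructureModel, reference: StructureModel,
            chain: str = "A", positions=None,
            frame_chain: str | None = None) -> float:
    """Cα RMSD over paired residues of ``chain`` (by residue number).

    With ``frame_chain`` set (e.g. the receptor chain), the superposition
    is computed on that chain and the RMSD of ``chain`` is measured in
    that frame; otherwise the scored pairs themselves are superposed.
    """
    m, r = _paired_ca(model, reference, chain, positions)
    if frame_chain is None:
        return kabsch(r, m)[2]
    fm, fr = _paired_ca(model, reference, frame_chain)
    rot, t, _ = kabsch(fr, fm)
    m_t = m @ rot.T + t
    return float(np.sqrt(((r - m_t) ** 2).sum(axis=1).mean()))


def tm_d0(length: int) -> float:
    """TM-score distance scale for a reference of ``length`` residues,
    clamped below at 0.5 Å for short peptides."""
    if length <= 15:
        return 0.5
    return max(0.5, 1.24 * (length - 15) ** (1.0 / 3.0) - 1.8)


def tm_score(reference: StructureModel, model: StructureModel,
             chain: str = "A", positions=None, max_iter: int = 20) -> float:
    """TM-score of the model against the reference over paired Cα atoms.

    ``(1/L) Σ 1/(1 + (d_i/d0)^2)`` with L the number of reference residues
    scored.  The superposition is optimized by iterative Kabsch
    reweighting: start from the all-pair superposition, then repeatedly
    re-superpose on the pairs closer than d0 until the pair set is stable
    (at most ``max_iter`` rounds), keeping the best score seen.  Residues
    here are in fixed one-to-one correspondence through template numbering,
    so no fragment search is needed.
    """
    m, r = _paired_ca(model, reference, chain, positions)
    L = r.shape[0]
    d0 = tm_d0(L)

    def score_for(subset: np.ndarray) -> tuple[float, np.ndarray]:
        rot, t, _ = kabsch(r[subset], m[subset])
        d = np.sqrt((((m @ rot.T + t) - r) ** 2).sum(axis=1))
        return float(np.mean(1.0 / (1.0 + (d / d0) ** 2))), d

    subset = np.arange(L)
    best, d = score_for(subset)
    for _ in range(max_iter):
        new_subset = np.flatnonzero(d < d0)
        if new_subset.size < 3 or np.array_equal(new_subset, subset):
            break
        subset = new_subset
        s, d = score_for(subset)
        best = max(best, s)
    return best


# --------------------------------------------------------------------------
# Solvent accessibility and SAP

def _golden_spiral(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere."""
    i = np.arange(n, dtype=float)
    z = 1.0 - 2.0 * (i + 0.5) / n
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    theta = i * math.pi * (3.0 - math.sqrt(5.0))
    return np.column_stack([rho * np.cos(theta), rho * np.sin(theta), z])


def shrake_rupley(model: StructureModel, probe: float = 1.4,
                  n_points: int = 256) -> list[float]:
    """Per-atom solvent-accessible surface area (Å²).

    Sphere-point sampling on a golden-spiral point set; a test point on the
    probe-expanded sphere of atom i is accessible when it lies outside the
    probe-expanded sphere of every neighbour.  The result list follows
    ``model.iter_atoms()`` order.
    """
    if n_points < 64:
        raise ValueError("n_points must be at least 64")
    atoms = list(model.iter_atoms())
    coords = np.array([a.xyz for a in atoms])
    radii = np.array([VDW_RADII.get(a.element, VDW_FALLBACK) for a in atoms])
    sphere = _golden_spiral(n_points)
    ext = radii + probe
    areas: list[float] = []
    for i, atom in enumerate(atoms):
        # neighbours whose probe-expanded spheres can occlude atom i
        d = np.sqrt(((coords - coords[i]) ** 2).sum(axis=1))
        nb = np.flatnonzero((d < ext[i] + ext) & (np.arange(len(atoms)) != i))
        pts = coords[i] + ext[i] * sphere
        if nb.size:
            d2 = ((pts[:, None, :] - coords[nb][None, :, :]) ** 2).sum(axis=2)
            exposed = np.all(d2 >= (ext[nb] ** 2)[None, :], axis=1)
            frac = exposed.mean()
        else:
            frac = 1.0
        areas.append(float(4.0 * math.pi * ext[i] ** 2 * frac))
    return areas


@dataclass(frozen=True)
class SapParams:
    """Spatial-aggregation-propensity parameters.

    ``radius`` is the spatial neighbourhood (Å); exposure fractions are
    SASA over the fully exposed side-chain reference per residue type;
    hydrophobicity is the Gly-zeroed normalized scale.
    """

    radius: float = 5.0
    probe: float = 1.4
    n_points: int = 256
    hydrophobicity: dict[str, float] = field(
        default_factory=lambda: dict(SAP_HYDROPHOBICITY))
    reference_sasa: dict[str, float] = field(
        default_factory=lambda: dict(MAX_SIDECHAIN_SASA))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if any(v <= 0 for v in self.reference_sasa.values()):
            raise ValueError("reference SASA values must be positive")


def _residue_token(res_name: str) -> str:
    try:
        return ONE_LETTER[res_name]
    except KeyError:
        raise KeyError(f"residue type {res_name!r} missing from reference "
                       "tables") from None


def sap(model: StructureModel, params: SapParams | None = None,
        sasa: list[float] | None = None
        ) -> tuple[dict[tuple[str, int], float], float]:
    """Per-residue SAP and the positive-part aggregate.

    For residue r, SAP_r sums, over every side-chain atom j of the
    structure lying within ``params.radius`` of any atom of r, the atom's
    exposure fraction (SASA_j over the residue-type side-chain reference)
    times the residue-type hydrophobicity.  The aggregate is
    ``Σ_r max(SAP_r, 0)`` — only aggregation-prone patches count.
    """
    params = params or SapParams()
    atoms = list(model.iter_atoms())
    if sasa is None:
        sasa = shrake_rupley(model, params.probe, params.n_points)
    coords = np.array([a.xyz for a in atoms])
    sidechain = np.array([a.name not in BACKBONE_ATOMS for a in atoms])
    contrib = np.zeros(len(atoms))
    for j, atom in enumerate(atoms):
        if not sidechain[j]:
            continue
        tok = _residue_token(atom.res_name)
        contrib[j] = (sasa[j] / params.reference_sasa[tok]
                      * params.hydrophobicity[tok])

    per_residue: dict[tuple[str, int], float] = {}
    for chain in model.chains.values():
        for res in chain.residues.values():
            rc = np.array([a.xyz for a in res.atoms])
            # side-chain atoms within radius of any atom of this residue
            d2 = ((coords[:, None, :] - rc[None, :, :]) ** 2).sum(axis=2)
            near = (d2.min(axis=1) <= params.radius ** 2) & sidechain
            per_residue[(chain.id, res.number)] = float(contrib[near].sum())
    aggregate = float(sum(max(v, 0.0) for v in per_residue.values()))
    return per_residue, aggregate


# --------------------------------------------------------------------------
# Confidence metrics

def mean_plddt(model: StructureModel, chain: str = "A") -> float:
    """Mean per-residue pLDDT over one chain (0-100)."""
    if chain not in model.chains:
        raise KeyError(f"chain {chain!r} absent from model")
    values = [res.plddt for res in model.chains[chain].residues.values()
              if res.plddt is not None]
    if not values:
        raise ValueError(f"chain {chain!r} has no pLDDT values")
    return float(np.mean(values))


def interface_pae(pae: PAEMatrix, chain_a: str, chain_b: str) -> float:
    """Mean predicted aligned error over both inter-chain blocks.

    Every a->b and b->a entry is weighted equally; intra-chain entries are
    excluded.
    """
    rows_a = pae.chain_rows(chain_a)
    rows_b = pae.chain_rows(chain_b)
    if np.intersect1d(rows_a, rows_b).size:
        raise ValueError("chain index sets overlap")
    ab = pae.matrix[np.ix_(rows_a, rows_b)]
    ba = pae.matrix[np.ix_(rows_b, rows_a)]
    return float(np.concatenate([ab.ravel(), ba.ravel()]).mean())


# --------------------------------------------------------------------------
# Scores, thresholds, gate

@dataclass(frozen=True)
class StructScore:
    """Per-candidate structural metric values (affinity is external)."""

    tm: float | None = None
    ca_rmsd: float | None = None
    mean_plddt: float | None = None
    interface_pae: float | None = None
    sap_aggregate: float | None = None
    affinity: float | None = None


@dataclass(frozen=True)
class EfficacyThresholds:
    min_tm: float | None = None
    max_ca_rmsd: float | None = None
    min_mean_plddt: float | None = None
    max_interface_pae: float | None = None
    max_sap: float | None = None
    max_affinity: float | None = None


RMSD_FLOOR = 0.5  # Å; reference self-RMSD is 0, a pure ratio bound collapses


def derive_thresholds(reference: StructScore, slack: float = 0.1
                      ) -> EfficacyThresholds:
    """Bounds from the native reference complex, widened by ``slack``.

    Lower bounds scale by (1-slack), upper bounds by (1+slack); the RMSD
    bound is floored at 0.5 Å because the reference scored against itself
    gives zero.
    """
    if slack < 0:
        raise ValueError("slack must be nonnegative")
    req = ("tm", "ca_rmsd", "mean_plddt", "interface_pae")
    for name in req:
        if getattr(reference, name) is None:
            raise ValueError(f"reference score {name!r} missing")
    return EfficacyThresholds(
        min_tm=reference.tm * (1.0 - slack),
        max_ca_rmsd=max(reference.ca_rmsd, RMSD_FLOOR) * (1.0 + slack),
        min_mean_plddt=reference.mean_plddt * (1.0 - slack),
        max_interface_pae=reference.interface_pae * (1.0 + slack),
        max_sap=(None if reference.sap_aggregate is None
                 else max(reference.sap_aggregate, 0.0) * (1.0 + slack)),
        max_affinity=(None if reference.affinity is None
                      else reference.affinity * (1.0 - slack)
                      if reference.affinity < 0
                      else reference.affinity * (1.0 + slack)),
    )


def efficacy_gate(scores: StructScore, thresholds: EfficacyThresholds
                  ) -> GateResult:
    """Pass iff every set bound is satisfied; reasons list each violation."""
    checks = [
        ("tm", scores.tm, thresholds.min_tm, "min"),
        ("ca_rmsd", scores.ca_rmsd, thresholds.max_ca_rmsd, "max"),
        ("mean_plddt", scores.mean_plddt, thresholds.min_mean_plddt, "min"),
        ("interface_pae", scores.interface_pae,
         thresholds.max_interface_pae, "max"),
        ("sap_aggregate", scores.sap_aggregate, thresholds.max_sap, "max"),
        ("affinity", scores.affinity, thresholds.max_affinity, "max"),
    ]
    reasons: list[tuple[str, float | str, float | str]] = []
    for name, value, bound, sense in checks:
        if bound is None:
            continue
        if value is None:
            raise ValueError(f"score {name!r} required by thresholds but "
                             "missing")
        if (sense == "min" and value < bound) or \
                (sense == "max" and value > bound):
            reasons.append((f"{name}_{sense}", value, bound))
    return GateResult(passed=not reasons, reasons=tuple(reasons))


def score_complex(model: StructureModel, reference: StructureModel,
                  pae: PAEMatrix | None = None,
                  agonist_chain: str = "A", receptor_chain: str = "B",
                  sap_params: SapParams | None = None,
                  affinity: float | None = None) -> StructScore:
    """Assemble the full metric block for one predicted complex.

    TM-score and RMSD are computed on the agonist chain; when the receptor
    chain is present in both models its frame anchors the RMSD
    superposition (the shared-receptor convention), otherwise the agonist
    pairs themselves are superposed.
    """
    frame = (receptor_chain
             if receptor_chain in model.chains
             and receptor_chain in reference.chains else None)
    per_res_sap, sap_aggregate = sap(model, sap_params)
    return StructScore(
        tm=tm_score(reference, model, chain=agonist_chain),
        ca_rmsd=ca_rmsd(model, reference, chain=agonist_chain,
                        frame_chain=frame),
        mean_plddt=mean_plddt(model, agonist_chain),
        interface_pae=(None if pae is None else
                       interface_pae(pae, agonist_chain, receptor_chain)),
        sap_aggregate=sap_aggregate,
        affinity=affinity,
    )


def ingest_affinity(path: str | Path) -> dict[str, float]:
    """Read external binding-affinity scores (kcal/mol) from a TSV with
    columns ``id`` and ``affinity``; duplicate ids are rejected."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "id" not in df.columns or "affinity" not in df.columns:
        raise ValueError(f"{path}: expected columns 'id' and 'affinity'")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()
        raise ValueError(f"{path}: duplicate ids {dups}")
    values = pd.to_numeric(df["affinity"], errors="coerce")
    if values.isna().any() and len(df):
        bad = df.loc[values.isna(), "id"].tolist()
        raise ValueError(f"{path}: non-numeric affinity for {bad}")
    return dict(zip(df["id"], values.astype(float)))
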