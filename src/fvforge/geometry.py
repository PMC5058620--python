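"""Superposition and accuracy protocols.

All accuracies are backbone RMSDs ({N, CA, C, O}; configurable).  The region
protocols mirror standard antibody model assessment: the whole Fv is fitted
on all shared backbone atoms; a chain's framework on its FW backbone atoms;
a CDR loop is measured after fitting the framework only (no refit on the
loop), so loop error includes its displacement relative to the scaffold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem import CHI_ATOMS
from .fv_model import BACKBONE_ATOMS, REGION_FW, FvStructure, NumberedResidue, pos_key


class GeometryError(ValueError):
    pass


@dataclass
class RigidTransform:
    """Proper rotation + translation, applied as ``x @ R.T + t``."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self):
        self.rotation = np.asarray(self.rotation, dtype=float)
        self.translation = np.asarray(self.translation, dtype=float)
        r = self.rotation
        if not np.allclose(r @ r.T, np.eye(3), atol=1e-6) or abs(np.linalg.det(r) - 1) > 1e-6:
            raise GeometryError("rotation must be orthogonal with determinant +1")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return np.asarray(coords, dtype=float) @ self.rotation.T + self.translation


@dataclass
class RmsdReport:
    region: str
    atom_count: int
    rmsd: float
    fit_scope: str

    def __post_init__(self):
        if self.rmsd < 0 or self.atom_count <= 0:
            raise GeometryError("RMSD must be >= 0 over a positive atom count")

    def to_dict(self) -> dict:
        return {"region": self.region, "atom_count": self.atom_count,
                "rmsd": round(self.rmsd, 4), "fit_scope": self.fit_scope}


def rmsd_between(a: np.ndarray, b: np.ndarray) -> float:
    a, b = np.asarray(a, float), np.asarray(b, float)
    return float(np.sqrt(np.mean(np.sum((a - b) ** 2, axis=1))))


def kabsch_superpose(mobile: np.ndarray, reference: np.ndarray
                     ) -> tuple[RigidTransform, float]:
    """Least-squares rigid fit of ``mobile`` onto ``reference`` (paired points).

    Returns the optimal proper-rotation transform and the post-fit RMSD.
    Raises for fewer than 3 points or a degenerate (collinear) reference.
    """
    mobile = np.asarray(mobile, float)
    reference = np.asarray(reference, float)
    if mobile.shape != reference.shape or mobile.ndim != 2 or mobile.shape[1] != 3:
        raise GeometryError("paired (n, 3) coordinate sets required")
    n = len(mobile)
    if n < 3:
        raise GeometryError(f"need >= 3 points for a rigid fit, got {n}")
    ref_c = reference - reference.mean(axis=0)
    if np.linalg.matrix_rank(ref_c, tol=1e-8) < 2:
        raise GeometryError("degenerate (collinear) reference coordinates")
    mob_c = mobile - mobile.mean(axis=0)
    h = mob_c.T @ ref_c
    u, _s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    trans = reference.mean(axis=0) - rot @ mobile.mean(axis=0)
    tf = RigidTransform(rot, trans)
    return tf, rmsd_between(tf.apply(mobile), reference)


def _paired_backbone(model: FvStructure, native: FvStructure, chain_type: str,
                     region: str | None = None,
                     atoms: tuple[str, ...] = BACKBONE_ATOMS
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Backbone coordinate pairs over shared positions (optionally one region)."""
    mmap = model.residue_map(chain_type)
    nmap = native.residue_map(chain_type)
    a, b = [], []
    for pos in sorted(set(mmap) & set(nmap), key=pos_key):
        rm, rn = mmap[pos], nmap[pos]
        if region is not None and (rm.region != region or rn.region != region):
            continue
        am = [rm.atom(x) for x in atoms]
        an = [rn.atom(x) for x in atoms]
        if any(x is None for x in am + an):
            warnings.warn(f"chain {chain_type} {pos}: incomplete backbone, residue "
                          "dropped from RMSD")
            continue
        a.extend(x.coord for x in am)
        b.extend(x.coord for x in an)
    return np.array(a), np.array(b)


def fv_rmsd(model: FvStructure, native: FvStructure,
            atoms: tuple[str, ...] = BACKBONE_ATOMS) -> RmsdReport:
    """Whole-Fv backbone RMSD, fitted on all shared backbone atoms of all chains."""
    pairs = [_paired_backbone(model, native, ct, atoms=atoms)
             for ct in model.chains if native.has_chain(ct)]
    pairs = [p for p in pairs if len(p[0])]
    if not pairs:
        raise GeometryError("no shared backbone atoms between model and native")
    a = np.vstack([p[0] for p in pairs])
    b = np.vstack([p[1] for p in pairs])
    if len(a) < 3:
        raise GeometryError("fewer than 3 shared backbone atoms")
    _tf, rmsd = kabsch_superpose(a, b)
    return RmsdReport("Fv", len(a), rmsd, "all shared backbone atoms")


def framework_rmsd(model: FvStructure, native: FvStructure, chain_type: str,
                   atoms: tuple[str, ...] = BACKBONE_ATOMS) -> RmsdReport:
    """One chain's framework backbone RMSD after fitting those same atoms."""
    a, b = _paired_backbone(model, native, chain_type, REGION_FW, atoms)
    if len(a) < 3:
        raise GeometryError(f"fewer than 3 shared FW backbone atoms on chain {chain_type}")
    _tf, rmsd = kabsch_superpose(a, b)
    return RmsdReport(f"FW-{chain_type}", len(a), rmsd,
                      f"chain {chain_type} framework backbone")


def cdr_rmsd(model: FvStructure, native: FvStructure, chain_type: str,
             cdr_index: int, both_chains_fit: bool = False,
             atoms: tuple[str, ...] = BACKBONE_ATOMS) -> RmsdReport:
    """CDR loop backbone RMSD after a framework-only fit (no refit on the loop).

    By default the fit uses the loop's own chain framework; with
    ``both_chains_fit`` both chains' frameworks are fitted first, a stricter
    protocol that also penalizes inter-domain orientation error.
    """
    region = f"CDR{cdr_index}"
    fit_chains = model.chains if both_chains_fit else [chain_type]
    fa, fb = [], []
    for ct in fit_chains:
        if not native.has_chain(ct):
            continue
        a, b = _paired_backbone(model, native, ct, REGION_FW, atoms)
        if len(a):
            fa.append(a)
            fb.append(b)
    if not fa:
        raise GeometryError("no shared framework atoms to fit")
    tf, _ = kabsch_superpose(np.vstack(fa), np.vstack(fb))

    mloop = [r for r in model.domain(chain_type) if r.region == region]
    nloop = [r for r in native.domain(chain_type) if r.region == region]
    mpos = [r.position for r in mloop]
    npos = [r.position for r in nloop]
    if mpos != npos:
        raise GeometryError(
            f"{region}-{chain_type} length/position mismatch between model "
            f"({len(mpos)} residues) and native ({len(npos)}); no partial-loop RMSD")
    la, lb = _paired_backbone(model, native, chain_type, region, atoms)
    if not len(la):
        raise GeometryError(f"no shared {region} atoms on chain {chain_type}")
    rmsd = rmsd_between(tf.apply(la), lb)
    scope = "both chains' framework backbone" if both_chains_fit else \
        f"chain {chain_type} framework backbone"
    return RmsdReport(f"{region}-{chain_type}", len(la), rmsd, scope)


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention, (-180, 180]."""
    p1, p2, p3, p4 = (np.asarray(p, float) for p in (p1, p2, p3, p4))
    b1, b2, b3 = p2 - p1, p3 - p2, p4 - p3
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    ang = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    return 180.0 if np.isclose(ang, -180.0) else float(ang)


def residue_chi(residue: NumberedResidue, k: int = 1) -> float | None:
    """chi_k of a residue from its atoms, or None when atoms are missing."""
    quads = CHI_ATOMS.get(residue.aa, [])
    if k > len(quads):
        return None
    atoms = [residue.atom(n) for n in quads[k - 1]]
    if any(a is None for a in atoms):
        return None
    return dihedral(*(a.coord for a in atoms))


def circular_difference(a: float, b: float) -> float:
    """Absolute angular difference in degrees, wrapped to [0, 180]."""
    d = abs(a - b) % 360.0
    return min(d, 360.0 - d)


def chi1_accuracy(model: FvStructure, native: FvStructure,
                  tolerance: float = 40.0, through_chi2: bool = False) -> float:
    """Percent of shared residues whose chi1 is within ``tolerance`` degrees of native.

    Gly/Ala (no chi1) and residues with missing side-chain atoms are excluded.
    With ``through_chi2`` a residue counts correct only if chi1 AND chi2 (where
    defined) are both within tolerance.
    """
    total = correct = 0
    for ct in model.chains:
        if not native.has_chain(ct):
            continue
        mmap = model.residue_map(ct)
        nmap = native.residue_map(ct)
        for pos in set(mmap) & set(nmap):
            rm, rn = mmap[pos], nmap[pos]
            if rm.aa != rn.aa or not CHI_ATOMS.get(rm.aa):
                continue
            ks = [1, 2] if through_chi2 and len(CHI_ATOMS[rm.aa]) >= 2 else [1]
            vals = [(residue_chi(rm, k), residue_chi(rn, k)) for k in ks]
            if any(v is None or w is None for v, w in vals):
                continue
            total += 1
            if all(circular_difference(v, w) <= tolerance for v, w in vals):
                correct += 1
    if total == 0:
        raise GeometryError("no comparable residues with side-chain torsions")
    return 100.0 * correct / total
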