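"""Residue chemistry: idealized internal coordinates, side-chain topology and torsions.

Heavy-atom topologies for the 20 standard amino acids, built with ideal bond
lengths/angles via the natural-extension-reference-frame (NeRF) construction.
Side-chain torsions (chi1..chi4) follow the standard N-CA-CB-XG (etc.) atom
quadruples; ring and branch atoms are placed at fixed torsion offsets.
Geometry is idealized, not energy-minimized: sufficient for torsion-accurate
rotamer placement, clash detection and surface-area estimates.
"""

from __future__ import annotations

import numpy as np

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}
AMINO_ACIDS = sorted(AA1_TO_3)

BACKBONE_ATOMS = ("N", "CA", "C", "O")

# chi-defining fourth atoms; chi1 = N-CA-CB-<atom>, chi2 = CA-CB-<g>-<atom>, ...
CHI_ATOMS: dict[str, list[tuple[str, str, str, str]]] = {
    "R": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "NE"), ("CG", "CD", "NE", "CZ")],
    "N": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "D": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "OD1")],
    "C": [("N", "CA", "CB", "SG")],
    "Q": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "E": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "OE1")],
    "H": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "ND1")],
    "I": [("N", "CA", "CB", "CG1"), ("CA", "CB", "CG1", "CD1")],
    "L": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "K": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD"),
          ("CB", "CG", "CD", "CE"), ("CG", "CD", "CE", "NZ")],
    "M": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "SD"),
          ("CB", "CG", "SD", "CE")],
    "F": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "P": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD")],
    "S": [("N", "CA", "CB", "OG")],
    "T": [("N", "CA", "CB", "OG1")],
    "W": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "Y": [("N", "CA", "CB", "CG"), ("CA", "CB", "CG", "CD1")],
    "V": [("N", "CA", "CB", "CG1")],
    "A": [], "G": [],
}

# torsion spec: ("chi", k, offset_deg) or ("fixed", deg)
_CB = ("CB", "C", ("C", "N", "CA"), 1.53, 110.5, ("fixed", -122.6))

SIDE_CHAIN_TOPOLOGY: dict[str, list[tuple]] = {
    "G": [],
    "A": [_CB],
    "S": [_CB, ("OG", "O", ("N", "CA", "CB"), 1.42, 110.8, ("chi", 1, 0.0))],
    "C": [_CB, ("SG", "S", ("N", "CA", "CB"), 1.81, 114.0, ("chi", 1, 0.0))],
    "T": [_CB, ("OG1", "O", ("N", "CA", "CB"), 1.43, 109.5, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -120.0))],
    "V": [_CB, ("CG1", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, 122.0))],
    "L": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.53, 116.3, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.52, 110.7, ("chi", 2, 122.0))],
    "I": [_CB, ("CG1", "C", ("N", "CA", "CB"), 1.53, 110.4, ("chi", 1, 0.0)),
          ("CG2", "C", ("N", "CA", "CB"), 1.52, 110.5, ("chi", 1, -122.0)),
          ("CD1", "C", ("CA", "CB", "CG1"), 1.52, 113.9, ("chi", 2, 0.0))],
    "M": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
          ("SD", "S", ("CA", "CB", "CG"), 1.80, 112.7, ("chi", 2, 0.0)),
          ("CE", "C", ("CB", "CG", "SD"), 1.79, 100.9, ("chi", 3, 0.0))],
    "P": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.49, 104.5, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.50, 106.1, ("chi", 2, 0.0))],
    "F": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, ("fixed", 180.0)),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, ("fixed", 180.0)),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fixed", 0.0))],
    "Y": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.50, 113.8, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.39, 120.0, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "CD1"), 1.39, 120.0, ("fixed", 180.0)),
          ("CE2", "C", ("CB", "CG", "CD2"), 1.39, 120.0, ("fixed", 180.0)),
          ("CZ", "C", ("CG", "CD1", "CE1"), 1.39, 120.0, ("fixed", 0.0)),
          ("OH", "O", ("CD1", "CE1", "CZ"), 1.38, 120.0, ("fixed", 180.0))],
    "W": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.50, 113.6, ("chi", 1, 0.0)),
          ("CD1", "C", ("CA", "CB", "CG"), 1.37, 127.0, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.43, 126.6, ("chi", 2, 180.0)),
          ("NE1", "N", ("CB", "CG", "CD1"), 1.38, 110.2, ("fixed", 180.0)),
          ("CE2", "C", ("CG", "CD1", "NE1"), 1.37, 109.0, ("fixed", 0.0)),
          ("CE3", "C", ("CB", "CG", "CD2"), 1.40, 133.9, ("fixed", 0.0)),
          ("CZ2", "C", ("CD1", "NE1", "CE2"), 1.40, 122.4, ("fixed", 180.0)),
          ("CZ3", "C", ("CG", "CD2", "CE3"), 1.39, 118.8, ("fixed", 180.0)),
          ("CH2", "C", ("CD2", "CE3", "CZ3"), 1.37, 121.1, ("fixed", 0.0))],
    "H": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.49, 113.7, ("chi", 1, 0.0)),
          ("ND1", "N", ("CA", "CB", "CG"), 1.38, 122.8, ("chi", 2, 0.0)),
          ("CD2", "C", ("CA", "CB", "CG"), 1.35, 131.0, ("chi", 2, 180.0)),
          ("CE1", "C", ("CB", "CG", "ND1"), 1.32, 109.2, ("fixed", 180.0)),
          ("NE2", "N", ("CG", "ND1", "CE1"), 1.33, 108.2, ("fixed", 0.0))],
    "D": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 113.0, ("chi", 1, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.25, 119.2, ("chi", 2, 0.0)),
          ("OD2", "O", ("CA", "CB", "CG"), 1.25, 118.2, ("chi", 2, 180.0))],
    "N": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 112.7, ("chi", 1, 0.0)),
          ("OD1", "O", ("CA", "CB", "CG"), 1.23, 120.8, ("chi", 2, 0.0)),
          ("ND2", "N", ("CA", "CB", "CG"), 1.33, 116.5, ("chi", 2, 180.0))],
    "E": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.25, 118.3, ("chi", 3, 0.0)),
          ("OE2", "O", ("CB", "CG", "CD"), 1.25, 118.3, ("chi", 3, 180.0))],
    "Q": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 112.6, ("chi", 2, 0.0)),
          ("OE1", "O", ("CB", "CG", "CD"), 1.23, 120.8, ("chi", 3, 0.0)),
          ("NE2", "N", ("CB", "CG", "CD"), 1.33, 116.6, ("chi", 3, 180.0))],
    "K": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
          ("CE", "C", ("CB", "CG", "CD"), 1.52, 111.3, ("chi", 3, 0.0)),
          ("NZ", "N", ("CG", "CD", "CE"), 1.49, 111.9, ("chi", 4, 0.0))],
    "R": [_CB, ("CG", "C", ("N", "CA", "CB"), 1.52, 114.1, ("chi", 1, 0.0)),
          ("CD", "C", ("CA", "CB", "CG"), 1.52, 111.3, ("chi", 2, 0.0)),
          ("NE", "N", ("CB", "CG", "CD"), 1.46, 112.0, ("chi", 3, 0.0)),
          ("CZ", "C", ("CG", "CD", "NE"), 1.33, 124.2, ("chi", 4, 0.0)),
          ("NH1", "N", ("CD", "NE", "CZ"), 1.33, 120.0, ("fixed", 0.0)),
          ("NH2", "N", ("CD", "NE", "CZ"), 1.33, 120.0, ("fixed", 180.0))],
}

#: full heavy-atom complement per residue type (backbone + side chain)
RESIDUE_ATOMS: dict[str, tuple[str, ...]] = {
    aa: BACKBONE_ATOMS + tuple(entry[0] for entry in topo)
    for aa, topo in SIDE_CHAIN_TOPOLOGY.items()
}


def n_chi(aa: str) -> int:
    """Number of side-chain torsions for a residue type (0 for Gly/Ala)."""
    return len(CHI_ATOMS.get(aa, []))


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Position atom X bonded to c, with angle b-c-X and torsion a-b-c-X (NeRF)."""
    angle = np.deg2rad(angle_deg)
    torsion = np.deg2rad(torsion_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    nn = np.linalg.norm(n)
    if nn < 1e-10:
        raise ValueError("collinear reference atoms in NeRF placement")
    n /= nn
    m = np.cross(n, bc)
    d = np.array([-bond * np.cos(angle),
                  bond * np.sin(angle) * np.cos(torsion),
                  -bond * np.sin(angle) * np.sin(torsion)])
    return c + d[0] * bc + d[1] * m + d[2] * n


def build_side_chain(aa: str, backbone: dict[str, np.ndarray],
                     chis: tuple[float, ...] | list[float]) -> list[tuple[str, str, np.ndarray]]:
    """Construct side-chain heavy atoms for ``aa`` on the given backbone.

    ``backbone`` must supply N, CA and C coordinates.  ``chis`` supplies one
    torsion (degrees) per chi angle of the residue type; extra values are
    ignored, missing ones default to 180.  Returns (name, element, coord)
    triples in topology order (CB first).
    """
    if aa not in SIDE_CHAIN_TOPOLOGY:
        raise KeyError(f"no side-chain topology for residue type {aa!r}")
    coords = {k: np.asarray(backbone[k], dtype=float) for k in ("N", "CA", "C")}
    chis = tuple(chis)
    out = []
    for name, element, (a1, a2, a3), bond, angle, tor in SIDE_CHAIN_TOPOLOGY[aa]:
        if tor[0] == "chi":
            k, offset = tor[1], tor[2]
            base = chis[k - 1] if k - 1 < len(chis) else 180.0
            torsion = base + offset
        else:
            torsion = tor[1]
        coords[name] = place_atom(coords[a1], coords[a2], coords[a3],
                                  bond, angle, torsion)
        out.append((name, element, coords[name]))
    return out


# ideal trans-peptide internal coordinates
_BOND_N_CA, _BOND_CA_C, _BOND_C_N, _BOND_C_O = 1.458, 1.525, 1.329, 1.231
_ANG_N_CA_C, _ANG_CA_C_N, _ANG_C_N_CA, _ANG_CA_C_O = 111.0, 116.6, 121.7, 120.5


def build_backbone(phi_psi: list[tuple[float, float]],
                   omega: float = 180.0) -> list[dict[str, np.ndarray]]:
    """Build an ideal-geometry polypeptide backbone from (phi, psi) per residue.

    The first residue's phi is unused (no preceding carbonyl).  Returns a list
    of {N, CA, C, O} coordinate dicts; consecutive CA-CA distances are ~3.80 Å
    for a trans peptide.
    """
    n_res = len(phi_psi)
    if n_res == 0:
        return []
    res: list[dict[str, np.ndarray]] = []
    n = np.array([0.0, 0.0, 0.0])
    ca = np.array([_BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(_ANG_N_CA_C)
    c = ca + np.array([-_BOND_CA_C * np.cos(ang), _BOND_CA_C * np.sin(ang), 0.0])
    res.append({"N": n, "CA": ca, "C": c})
    for i in range(1, n_res):
        phi = phi_psi[i][0]
        psi_prev = phi_psi[i - 1][1]
        n_next = place_atom(res[-1]["N"], res[-1]["CA"], res[-1]["C"],
                            _BOND_C_N, _ANG_CA_C_N, psi_prev)
        ca_next = place_atom(res[-1]["CA"], res[-1]["C"], n_next,
                             _BOND_N_CA, _ANG_C_N_CA, omega)
        c_next = place_atom(res[-1]["C"], n_next, ca_next,
                            _BOND_CA_C, _ANG_N_CA_C, phi)
        res.append({"N": n_next, "CA": ca_next, "C": c_next})
    for i, r in enumerate(res):
        psi = phi_psi[i][1]
        r["O"] = place_atom(r["N"], r["CA"], r["C"], _BOND_C_O, _ANG_CA_C_O,
                            psi + 180.0)
    return res


def intra_residue_bonds(aa: str) -> list[tuple[str, str]]:
    """Covalent heavy-atom bond list within one residue (backbone + side chain)."""
    bonds = [("N", "CA"), ("CA", "C"), ("C", "O")]
    for name, _el, (_a1, _a2, a3), *_rest in SIDE_CHAIN_TOPOLOGY.get(aa, []):
        bonds.append((a3, name))
    # aromatic/ring closures not encoded by the NeRF parent chain
    closures = {
        "F": [("CE2", "CZ")], "Y": [("CE2", "CZ")],
        "H": [("CD2", "NE2")], "P": [("CD", "N")],
        "W": [("CD2", "CE2"), ("CZ2", "CH2"), ("CZ3", "CH2")],
    }
    bonds.extend(closures.get(aa, []))
    return bonds
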