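"""Side-chain completion and clash control.

Placement is rotamer-library driven: residues identical between template and
target keep the template side chain verbatim ("partial" prediction, the
default); differing residues are rebuilt from ideal internal geometry using
the most probable rotamer that introduces no new clash.  Two atoms clash when
their distance is below 65% of the sum of their van der Waals radii (strict
less-than); covalently bonded pairs and 1-3 neighbours are exempt.  Clash
resolution is staged: first only the clashing residues are re-sampled, then,
if needed, all side chains.
"""

from __future__ import annotations

import importlib.resources
import json
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree

from .chem import (CHI_ATOMS, RESIDUE_ATOMS, build_side_chain,
                   intra_residue_bonds, n_chi)
from .fv_model import AtomRecord, FvStructure, NumberedResidue, pos_key

DEFAULT_CLASH_FACTOR = 0.65


class SideChainError(ValueError):
    pass


class VdwRadiusTable:
    """Element -> van der Waals radius (Å); carbon is 1.7 Å in the bundled table."""

    def __init__(self, radii: dict[str, float] | None = None):
        if radii is None:
            radii = self._load_default()
        if any(r <= 0 for r in radii.values()):
            raise SideChainError("van der Waals radii must be positive")
        self.radii = dict(radii)

    @staticmethod
    def _load_default() -> dict[str, float]:
        path = importlib.resources.files("fvforge.data") / "vdw_radii.tsv"
        out = {}
        for line in path.read_text().splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            el, r = line.split("\t")
            out[el] = float(r)
        return out

    def __getitem__(self, element: str) -> float:
        try:
            return self.radii[element.upper()]
        except KeyError:
            raise SideChainError(f"element {element!r} has no van der Waals radius "
                                 "in the table") from None


class RotamerLibrary:
    """Residue type -> (chi tuple, prior probability) list, most probable first."""

    def __init__(self, rotamers: dict[str, list[tuple[tuple[float, ...], float]]]):
        self.rotamers = {}
        for aa, rots in rotamers.items():
            rots = sorted(rots, key=lambda r: -r[1])
            if rots:
                total = sum(p for _c, p in rots)
                if abs(total - 1.0) > 1e-6:
                    raise SideChainError(f"{aa}: rotamer probabilities sum to {total}")
            self.rotamers[aa] = [(tuple(c), p) for c, p in rots]

    @classmethod
    def load(cls, path=None) -> "RotamerLibrary":
        if path is None:
            path = importlib.resources.files("fvforge.data") / "rotamers.json"
        data = json.loads(path.read_text() if hasattr(path, "read_text")
                          else open(path).read())
        return cls({aa: [(tuple(e["chi"]), e["p"]) for e in rots]
                    for aa, rots in data.items()})

    def __call__(self, aa: str) -> list[tuple[tuple[float, ...], float]]:
        try:
            return self.rotamers[aa]
        except KeyError:
            raise SideChainError(f"residue type {aa!r} absent from rotamer library") \
                from None


@dataclass
class ClashReport:
    pairs: list[tuple[tuple, tuple, float, float]] = field(default_factory=list)

    def __post_init__(self):
        if any(d >= t for _a, _b, d, t in self.pairs):
            raise SideChainError("clash report may only list distances below threshold")

    @property
    def clash_free(self) -> bool:
        return not self.pairs

    def __len__(self) -> int:
        return len(self.pairs)

    def residues(self) -> set[tuple[str, tuple]]:
        out = set()
        for a, b, _d, _t in self.pairs:
            out.add((a[0], a[1]))
            out.add((b[0], b[1]))
        return out

    def to_json(self) -> str:
        return json.dumps({
            "clash_free": self.clash_free,
            "clashes": [{"atom_a": [a[0], f"{a[1][0]}{a[1][1]}", a[2]],
                         "atom_b": [b[0], f"{b[1][0]}{b[1][1]}", b[2]],
                         "distance": round(d, 3), "threshold": round(t, 3)}
                        for a, b, d, t in self.pairs]})


def clash_pairs(coords: np.ndarray, radii: np.ndarray,
                factor: float = DEFAULT_CLASH_FACTOR,
                exclusions: dict[int, set[int]] | None = None
                ) -> list[tuple[int, int, float, float]]:
    """All atom index pairs with distance strictly below factor*(r_i + r_j).

    ``exclusions`` maps an atom index to indices exempt from the check
    (covalent 1-2 and 1-3 neighbours).  KD-tree accelerated; equivalent to the
    brute-force pairwise check.
    """
    coords = np.asarray(coords, float)
    radii = np.asarray(radii, float)
    tree = cKDTree(coords)
    cutoff = factor * 2.0 * radii.max()
    out = []
    for i, j in tree.query_pairs(cutoff):
        if exclusions and j in exclusions.get(i, ()):
            continue
        d = float(np.linalg.norm(coords[i] - coords[j]))
        thr = factor * (radii[i] + radii[j])
        if d < thr:
            out.append((min(i, j), max(i, j), d, thr))
    return sorted(out)


class _AtomIndex:
    """Flattened atom view of a structure with covalent exclusion sets."""

    def __init__(self, fv: FvStructure, table: VdwRadiusTable):
        self.keys: list[tuple[str, tuple, str]] = []   # (chain, pos, atom name)
        coords, radii = [], []
        node = {}
        adj: dict[int, set[int]] = {}

        def add_edge(i, j):
            adj.setdefault(i, set()).add(j)
            adj.setdefault(j, set()).add(i)

        for ct in fv.chains:
            prev_c = None
            for r in fv.domain(ct):
                for a in r.atoms:
                    idx = len(self.keys)
                    node[(ct, r.position, a.name)] = idx
                    self.keys.append((ct, r.position, a.name))
                    coords.append(a.coord)
                    radii.append(table[a.element])
                names = {a.name for a in r.atoms}
                for x, y in intra_residue_bonds(r.aa):
                    if x in names and y in names:
                        add_edge(node[(ct, r.position, x)], node[(ct, r.position, y)])
                if prev_c is not None and "N" in names:
                    add_edge(prev_c, node[(ct, r.position, "N")])
                prev_c = node.get((ct, r.position, "C"))
        self.coords = np.array(coords) if coords else np.zeros((0, 3))
        self.radii = np.array(radii)
        # 1-2 and 1-3 neighbourhoods
        self.exclusions = {}
        for i, nbrs in adj.items():
            ex = set(nbrs)
            for j in nbrs:
                ex |= adj.get(j, set())
            ex.discard(i)
            self.exclusions[i] = ex


def detect_clashes(fv: FvStructure, table: VdwRadiusTable | None = None,
                   factor: float = DEFAULT_CLASH_FACTOR) -> ClashReport:
    """Report all non-bonded atom pairs closer than factor x (sum of vdW radii)."""
    table = table or VdwRadiusTable()
    index = _AtomIndex(fv, table)
    pairs = clash_pairs(index.coords, index.radii, factor, index.exclusions)
    return ClashReport([(index.keys[i], index.keys[j], d, t)
                        for i, j, d, t in pairs])


def _rebuild_residue(res: NumberedResidue, chis: tuple[float, ...]) -> None:
    backbone = {n: res.atom(n).coord for n in ("N", "CA", "C")}
    res.strip_side_chain()
    for name, element, coord in build_side_chain(res.aa, backbone, chis):
        res.atoms.append(AtomRecord(name, element, coord))


def _residue_clash_count(fv: FvStructure, table: VdwRadiusTable, factor: float,
                         chain: str, pos: tuple) -> int:
    """Clash pairs involving the side chain of one residue."""
    index = _AtomIndex(fv, table)
    from .chem import BACKBONE_ATOMS
    own = {i for i, k in enumerate(index.keys)
           if k[0] == chain and k[1] == pos and k[2] not in BACKBONE_ATOMS}
    if not own:
        return 0
    count = 0
    tree = cKDTree(index.coords)
    cutoff = factor * 2.0 * index.radii.max()
    for i in own:
        for j in tree.query_ball_point(index.coords[i], cutoff):
            if j == i or (j in own and j < i):
                continue
            if j in index.exclusions.get(i, ()):
                continue
            d = np.linalg.norm(index.coords[i] - index.coords[j])
            if d < factor * (index.radii[i] + index.radii[j]):
                count += 1
    return count


def _place_best_rotamer(fv: FvStructure, res: NumberedResidue,
                        library: RotamerLibrary, table: VdwRadiusTable,
                        factor: float) -> None:
    """Set the residue's side chain to the most probable clash-free rotamer.

    Falls back to the least-clashing rotamer (ties to higher prior) when every
    candidate clashes.
    """
    rots = library(res.aa)
    if not rots:                       # Gly (nothing) / Ala (CB only)
        _rebuild_residue(res, ())
        return
    best = None
    for chis, _p in rots:              # already prior-ordered
        _rebuild_residue(res, chis)
        n = _residue_clash_count(fv, table, factor, res.chain_type, res.position)
        if n == 0:
            return
        if best is None or n < best[0]:
            best = (n, chis)
    _rebuild_residue(res, best[1])


def partial_side_chain_prediction(model: FvStructure, target_seq=None,
                                  library: RotamerLibrary | None = None,
                                  table: VdwRadiusTable | None = None,
                                  factor: float = DEFAULT_CLASH_FACTOR) -> FvStructure:
    """Retain template side chains of identical residues; rebuild the rest.

    ``target_seq`` may be an :class:`~fvforge.fv_model.FvSequence` or a
    ``{chain: {pos: aa}}`` mapping; when omitted, the model's own residue
    identities are the target and only residues with missing side-chain atoms
    are (re)built.  Backbone atoms are never moved.
    """
    library = library or RotamerLibrary.load()
    table = table or VdwRadiusTable()
    out = model.copy()
    targets = getattr(target_seq, "chains", target_seq)
    for ct in out.chains:
        tmap = targets.get(ct, {}) if targets else {}
        for res in out.domain(ct):
            target_aa = tmap.get(res.position, res.aa)
            expected = set(RESIDUE_ATOMS.get(target_aa, ()))
            have = {a.name for a in res.atoms}
            if res.aa == target_aa and expected <= have:
                continue
            res.aa = target_aa
            if not res.has_backbone():
                warnings.warn(f"{out.name}: {ct}{res.position[0]} lacks backbone, "
                              "side chain not built")
                continue
            _place_best_rotamer(out, res, library, table, factor)
    return out


def complete_side_chain_prediction(model: FvStructure, target_seq=None,
                                   library: RotamerLibrary | None = None,
                                   table: VdwRadiusTable | None = None,
                                   factor: float = DEFAULT_CLASH_FACTOR) -> FvStructure:
    """Rebuild every side chain from the library, ignoring template rotamers.

    Gly and Ala (no rotatable side chain) are left untouched.
    """
    library = library or RotamerLibrary.load()
    table = table or VdwRadiusTable()
    out = model.copy()
    targets = getattr(target_seq, "chains", target_seq)
    for ct in out.chains:
        tmap = targets.get(ct, {}) if targets else {}
        for res in out.domain(ct):
            res.aa = tmap.get(res.position, res.aa)
            if n_chi(res.aa) == 0:
                continue
            if not res.has_backbone():
                continue
            _place_best_rotamer(out, res, library, table, factor)
    return out


def resolve_clashes(fv: FvStructure, library: RotamerLibrary | None = None,
                    table: VdwRadiusTable | None = None,
                    factor: float = DEFAULT_CLASH_FACTOR
                    ) -> tuple[FvStructure, str]:
    """Staged clash relaxation: none -> local (clashing residues) -> global.

    Returns the first clash-free structure and its stage; if no stage reaches
    zero clashes, the minimum-clash-count structure is returned with a warning.
    The reported clash count never exceeds the input's.
    """
    library = library or RotamerLibrary.load()
    table = table or VdwRadiusTable()
    report0 = detect_clashes(fv, table, factor)
    if report0.clash_free:
        return fv, "none"

    local = fv.copy()
    involved = report0.residues()
    for ct in local.chains:
        for res in local.domain(ct):
            if (ct, res.position) in involved and n_chi(res.aa) > 0 and res.has_backbone():
                _place_best_rotamer(local, res, library, table, factor)
    report1 = detect_clashes(local, table, factor)
    if report1.clash_free:
        return local, "local"

    global_ = local.copy()
    for ct in global_.chains:
        for res in global_.domain(ct):
            if n_chi(res.aa) > 0 and res.has_backbone():
                _place_best_rotamer(global_, res, library, table, factor)
    report2 = detect_clashes(global_, table, factor)
    if report2.clash_free:
        return global_, "global"

    candidates = [(len(report2), 0, global_), (len(report1), 1, local),
                  (len(report0), 2, fv)]
    n, _rank, best = min(candidates, key=lambda c: (c[0], c[1]))
    warnings.warn(f"{fv.name}: {n} clash(es) remain after global side-chain "
                  "refinement")
    return best, "global"
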