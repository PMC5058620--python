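"""Core data model for numbered antibody variable domains.

An :class:`FvStructure` holds one or two variable domains (VH and/or VL) as
ordered lists of numbered residues.  Residue numbering follows the active
scheme (sequential consensus positions by default); complementarity-
determining regions (CDR1/2/3) versus framework (FW) are assigned from a
bundled, editable interval table.  PDB-format I/O goes through gemmi.
"""

from __future__ import annotations

import copy as _copy
import importlib.resources
import warnings
from dataclasses import dataclass, field

import gemmi
import numpy as np
from Bio import Align, SeqIO
from Bio.Align import substitution_matrices

from .chem import AA1_TO_3, AA3_TO_1, AMINO_ACIDS, BACKBONE_ATOMS

#: scheme position: (number, insertion code); '' sorts before 'A'
Pos = tuple[int, str]

REGION_FW = "FW"
CDR_REGIONS = ("CDR1", "CDR2", "CDR3")

#: scheme positions of the conserved intra-domain disulfide cysteine pair
CANONICAL_CYS_POSITIONS = (23, 104)


class FvModelError(ValueError):
    pass


class NumberingError(FvModelError):
    """Sequence could not be assigned scheme positions."""


def pos_key(p: Pos) -> tuple[int, str]:
    return (p[0], p[1])


def format_pos(p: Pos) -> str:
    return f"{p[0]}{p[1]}"


@dataclass
class AtomRecord:
    name: str
    element: str
    coord: np.ndarray
    occupancy: float = 1.0
    b_factor: float = 0.0

    def __post_init__(self):
        self.coord = np.asarray(self.coord, dtype=float)
        if self.coord.shape != (3,) or not np.all(np.isfinite(self.coord)):
            raise FvModelError(f"atom {self.name}: coordinates must be 3 finite values")

    def copy(self) -> "AtomRecord":
        return AtomRecord(self.name, self.element, self.coord.copy(),
                          self.occupancy, self.b_factor)


@dataclass
class NumberedResidue:
    chain_type: str          # 'H' or 'L'
    position: Pos
    aa: str                  # one-letter code, 'X' for non-standard
    atoms: list[AtomRecord] = field(default_factory=list)
    region: str | None = None  # None until assign_regions; then FW/CDR1/CDR2/CDR3

    def __post_init__(self):
        if self.aa not in AMINO_ACIDS and self.aa != "X":
            raise FvModelError(f"unknown residue code {self.aa!r}")

    def atom(self, name: str) -> AtomRecord | None:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def has_backbone(self) -> bool:
        names = {a.name for a in self.atoms}
        return all(n in names for n in BACKBONE_ATOMS)

    def backbone_coords(self) -> np.ndarray:
        """(4, 3) array in N, CA, C, O order."""
        return np.array([self.atom(n).coord for n in BACKBONE_ATOMS])

    def side_chain_atoms(self) -> list[AtomRecord]:
        return [a for a in self.atoms if a.name not in BACKBONE_ATOMS]

    def strip_side_chain(self) -> None:
        self.atoms = [a for a in self.atoms if a.name in BACKBONE_ATOMS]

    def copy(self) -> "NumberedResidue":
        return NumberedResidue(self.chain_type, self.position, self.aa,
                               [a.copy() for a in self.atoms], self.region)


@dataclass
class FvStructure:
    """One or two numbered variable domains with region labels."""

    heavy: list[NumberedResidue] | None = None
    light: list[NumberedResidue] | None = None
    name: str = ""
    scheme: str = "consensus"
    cdr_definition: str | None = None

    def __post_init__(self):
        if self.heavy is None and self.light is None:
            raise FvModelError("FvStructure needs at least one domain")
        for dom in (self.heavy, self.light):
            if dom is None:
                continue
            keys = [pos_key(r.position) for r in dom]
            if keys != sorted(keys) or len(set(keys)) != len(keys):
                raise FvModelError("residues must be strictly ordered by scheme position")

    @property
    def chains(self) -> list[str]:
        out = []
        if self.heavy is not None:
            out.append("H")
        if self.light is not None:
            out.append("L")
        return out

    def domain(self, chain_type: str) -> list[NumberedResidue]:
        dom = self.heavy if chain_type == "H" else self.light if chain_type == "L" else None
        if dom is None:
            raise FvModelError(f"structure {self.name!r} has no chain {chain_type!r}")
        return dom

    def has_chain(self, chain_type: str) -> bool:
        return chain_type in self.chains

    def is_paired(self) -> bool:
        return self.heavy is not None and self.light is not None

    def residue_map(self, chain_type: str) -> dict[Pos, NumberedResidue]:
        return {r.position: r for r in self.domain(chain_type)}

    def sequence(self, chain_type: str) -> str:
        return "".join(r.aa for r in self.domain(chain_type))

    def numbered_sequence(self, chain_type: str) -> list[tuple[Pos, str]]:
        return [(r.position, r.aa) for r in self.domain(chain_type)]

    def region_residues(self, chain_type: str, region: str) -> list[NumberedResidue]:
        return [r for r in self.domain(chain_type) if r.region == region]

    def all_atoms(self) -> list[tuple[str, NumberedResidue, AtomRecord]]:
        out = []
        for ct in self.chains:
            for r in self.domain(ct):
                for a in r.atoms:
                    out.append((ct, r, a))
        return out

    def copy(self) -> "FvStructure":
        return FvStructure(
            heavy=[r.copy() for r in self.heavy] if self.heavy is not None else None,
            light=[r.copy() for r in self.light] if self.light is not None else None,
            name=self.name, scheme=self.scheme, cdr_definition=self.cdr_definition)


@dataclass
class FvSequence:
    """Numbered target sequences (no coordinates), one entry per chain."""

    chains: dict[str, dict[Pos, str]]
    name: str = ""

    @classmethod
    def from_structure(cls, fv: FvStructure) -> "FvSequence":
        return cls({ct: dict(fv.numbered_sequence(ct)) for ct in fv.chains}, fv.name)

    def positions(self, chain_type: str) -> list[Pos]:
        return sorted(self.chains[chain_type], key=pos_key)

    def fw_map(self, chain_type: str, defs: "CdrDefinitionTable") -> dict[Pos, str]:
        return {p: aa for p, aa in self.chains[chain_type].items()
                if defs.label(chain_type, p) == REGION_FW}

    def cdr_segment(self, chain_type: str, cdr_index: int,
                    defs: "CdrDefinitionTable") -> list[tuple[Pos, str]]:
        lab = f"CDR{cdr_index}"
        return sorted(((p, aa) for p, aa in self.chains[chain_type].items()
                       if defs.label(chain_type, p) == lab), key=lambda x: pos_key(x[0]))


class CdrDefinitionTable:
    """Inclusive CDR position intervals per chain type, for one definition set."""

    def __init__(self, intervals: dict[tuple[str, int], tuple[int, int]], name: str = ""):
        self.name = name
        self.intervals = dict(intervals)
        for ct in ("H", "L"):
            spans = sorted(self.intervals.get((ct, k)) for k in (1, 2, 3))
            if any(s is None for s in spans):
                raise FvModelError(f"definition table {name!r} incomplete for chain {ct}")
            for (a, b), (c, d) in zip(spans, spans[1:]):
                if b >= c:
                    raise FvModelError(f"overlapping CDR intervals on chain {ct}")

    @classmethod
    def load(cls, name: str = "north", path=None) -> "CdrDefinitionTable":
        """Load a named definition set from the bundled (or a user) TSV table."""
        if path is None:
            path = importlib.resources.files("fvforge.data") / "cdr_definitions.tsv"
        intervals = {}
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                set_name, ct, idx, start, end = line.split("\t")
                if set_name == name:
                    intervals[(ct, int(idx))] = (int(start), int(end))
        if not intervals:
            raise FvModelError(f"no CDR definition set named {name!r}")
        return cls(intervals, name)

    def interval(self, chain_type: str, cdr_index: int) -> tuple[int, int]:
        return self.intervals[(chain_type, cdr_index)]

    def label(self, chain_type: str, position: Pos) -> str:
        num = position[0]
        for k in (1, 2, 3):
            a, b = self.intervals[(chain_type, k)]
            if a <= num <= b:
                return f"CDR{k}"
        return REGION_FW


_ELEMENT_FALLBACK = {"N": "N", "C": "C", "O": "O", "S": "S", "H": "H", "P": "P"}


def _guess_element(atom_name: str) -> str:
    name = atom_name.strip()
    return _ELEMENT_FALLBACK.get(name[:1], name[:1])


def read_structure(path, chain_map: dict[str, str], name: str | None = None) -> FvStructure:
    """Read a PDB-format file into an :class:`FvStructure`.

    ``chain_map`` maps PDB chain ids to domain types, e.g. ``{"H": "H", "A": "L"}``.
    Residues keep their author numbering as scheme positions; region labels are
    unset until :func:`assign_regions`.  Non-standard residues are kept with
    code X and a warning.
    """
    st = gemmi.read_pdb(str(path))
    if len(st) == 0:
        raise FvModelError(f"{path}: no models in PDB file")
    model = st[0]
    present = {ch.name for ch in model}
    domains: dict[str, list[NumberedResidue]] = {}
    for chain_id, chain_type in chain_map.items():
        if chain_id not in present:
            raise FvModelError(f"{path}: chain {chain_id!r} not found "
                               f"(available: {sorted(present)})")
        if chain_type not in ("H", "L"):
            raise FvModelError(f"chain type must be H or L, got {chain_type!r}")
        residues = []
        for res in model[chain_id]:
            aa = AA3_TO_1.get(res.name.upper())
            if aa is None:
                warnings.warn(f"{path}: non-standard residue {res.name} "
                              f"{res.seqid.num}{res.seqid.icode.strip()} kept as X")
                aa = "X"
            atoms = [AtomRecord(a.name, a.element.name or _guess_element(a.name),
                                np.array([a.pos.x, a.pos.y, a.pos.z]),
                                a.occ, a.b_iso)
                     for a in res]
            pos = (res.seqid.num, res.seqid.icode.strip())
            residues.append(NumberedResidue(chain_type, pos, aa, atoms))
        residues.sort(key=lambda r: pos_key(r.position))
        domains[chain_type] = residues
    return FvStructure(heavy=domains.get("H"), light=domains.get("L"),
                       name=name if name is not None else str(path))


def write_structure(fv: FvStructure, path=None) -> str:
    """Write an :class:`FvStructure` as PDB text (chains H and L).

    Returns the PDB string; also writes it to ``path`` when given.
    """
    st = gemmi.Structure()
    st.name = fv.name or "model"
    model = gemmi.Model("1")
    for ct in fv.chains:
        chain = gemmi.Chain(ct)
        for r in fv.domain(ct):
            res = gemmi.Residue()
            res.name = AA1_TO_3.get(r.aa, "UNK")
            res.seqid = gemmi.SeqId(r.position[0], r.position[1] or " ")
            for a in r.atoms:
                atom = gemmi.Atom()
                atom.name = a.name
                atom.element = gemmi.Element(a.element)
                atom.pos = gemmi.Position(*a.coord)
                atom.occ = a.occupancy
                atom.b_iso = a.b_factor
                res.add_atom(atom)
            chain.add_residue(res)
        model.add_chain(chain)
    st.add_model(model)
    st.setup_entities()
    text = st.make_pdb_string()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text


def read_fasta(path) -> list[tuple[str, str]]:
    """Return (id, sequence) pairs from a FASTA file."""
    return [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]


def _load_consensus() -> dict[str, str]:
    path = importlib.resources.files("fvforge.data") / "consensus.fasta"
    out = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        out[rec.id.upper()] = str(rec.seq).upper()
    return out


_CONSENSUS_CACHE: dict[str, str] | None = None
_INSERTION_CODES = "ABCDEFGHIJKLMNOPQRSTUVWXYZ"


def consensus_sequence(chain_type: str) -> str:
    global _CONSENSUS_CACHE
    if _CONSENSUS_CACHE is None:
        _CONSENSUS_CACHE = _load_consensus()
    return _CONSENSUS_CACHE[chain_type]


def number_sequence(seq: str, chain_type: str, min_identity: float = 30.0,
                    ) -> list[tuple[Pos, str]]:
    """Assign scheme positions by global alignment to the bundled consensus.

    Consensus positions are numbered 1..n; target residues aligned to a
    consensus column inherit its number, extra target residues become
    insertion codes (A, B, ...) on the preceding position.  Deterministic for
    fixed gap penalties.  Raises :class:`NumberingError` when alignment
    identity to the consensus falls below ``min_identity`` percent.
    """
    seq = seq.upper()
    if not (60 <= len(seq) <= 200):
        raise NumberingError(f"sequence length {len(seq)} implausible for a "
                             "variable domain (expected 60-200 residues)")
    cons = consensus_sequence(chain_type)
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    aln = aligner.align(cons, seq)[0]
    cons_aln, seq_aln = str(aln[0]), str(aln[1])
    matches = sum(1 for a, b in zip(cons_aln, seq_aln) if a == b and a != "-")
    aligned = sum(1 for a, b in zip(cons_aln, seq_aln) if a != "-" and b != "-")
    identity = 100.0 * matches / max(aligned, 1)
    if identity < min_identity:
        raise NumberingError(
            f"unnumberable: {identity:.1f}% identity to the {chain_type} "
            f"consensus (floor {min_identity}%)")
    numbered: list[tuple[Pos, str]] = []
    cons_pos = 0
    ins = 0
    for c, t in zip(cons_aln, seq_aln):
        if c != "-":
            cons_pos += 1
            ins = 0
        if t == "-":
            continue
        if c != "-":
            numbered.append(((cons_pos, ""), t))
        else:
            anchor = max(cons_pos, 1)
            numbered.append(((anchor, _INSERTION_CODES[ins]), t))
            ins += 1
    return numbered


def assign_regions(fv: FvStructure, defs: CdrDefinitionTable) -> FvStructure:
    """Label every residue FW or CDR1/2/3 from the definition table (in place)."""
    for ct in fv.chains:
        dom = fv.domain(ct)
        for r in dom:
            r.region = defs.label(ct, r.position)
        for k in (1, 2, 3):
            if not any(r.region == f"CDR{k}" for r in dom):
                warnings.warn(f"{fv.name}: chain {ct} has an empty CDR{k} interval")
    fv.cdr_definition = defs.name
    return fv


def framework_sequence_identity(a: FvStructure | FvSequence,
                                b: FvStructure | FvSequence,
                                chain_type: str,
                                defs: CdrDefinitionTable | None = None) -> float:
    """Percent identity over shared framework scheme positions of one chain.

    Positions present in only one input are excluded from numerator and
    denominator.  Symmetric in its arguments.
    """
    maps = []
    for x in (a, b):
        if isinstance(x, FvSequence):
            if defs is None:
                raise FvModelError("defs required to locate FW positions of a sequence")
            maps.append(x.fw_map(chain_type, defs))
        else:
            fw = {r.position: r.aa for r in x.domain(chain_type) if r.region == REGION_FW}
            if not fw and defs is not None:
                fw = {r.position: r.aa for r in x.domain(chain_type)
                      if defs.label(chain_type, r.position) == REGION_FW}
            maps.append(fw)
    shared = set(maps[0]) & set(maps[1])
    if not shared:
        raise FvModelError("no shared framework positions between the two structures")
    same = sum(1 for p in shared if maps[0][p] == maps[1][p])
    return 100.0 * same / len(shared)
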