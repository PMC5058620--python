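"""Developability sequence-liability scanning with solvent-exposure gating.

Matching is purely sequence-based (per chain, in scheme-position order, with
overlapping matches allowed); a hit is only reported as *exposed* when the
maximum relative accessible surface area over its span exceeds the exposure
threshold (strictly greater than 10% by default).  Relative ASA is absolute
Shrake-Rupley ASA (1.4 Å probe) normalized by a per-residue-type maximum
(theoretical Gly-X-Gly reference values), in percent.

The bundled motif table (editable TSV) covers N-glycosylation (Asn-X-Ser/Thr,
X unrestricted by default; an X != Pro refinement is available), asparagine
deamidation, aspartate isomerization, Met/Trp oxidation, lysine glycation,
unpaired cysteines outside the canonical intra-domain pair, and N-terminal
pyroglutamate formation.
"""

from __future__ import annotations

import importlib.resources
import io
import json
import re
import warnings
from dataclasses import dataclass, field

from Bio.PDB import PDBParser
from Bio.PDB.SASA import ShrakeRupley

from .fv_model import (CANONICAL_CYS_POSITIONS, FvStructure, Pos, pos_key,
                       write_structure)

DEFAULT_EXPOSURE_THRESHOLD = 10.0   # percent relative ASA


class LiabilityError(ValueError):
    pass


@dataclass
class LiabilityMotif:
    name: str
    kind: str                     # 'regex' | 'unpaired_cys' | 'nterm'
    pattern: str
    regions: str = "all"          # 'all' | 'cdr' | 'fw'
    note: str = ""

    def __post_init__(self):
        if self.kind == "regex" and len(self.pattern) < 1:
            raise LiabilityError(f"motif {self.name}: empty pattern")

    def applies_to(self, region: str | None) -> bool:
        if self.regions == "all" or region is None:
            return True
        if self.regions == "cdr":
            return region.startswith("CDR")
        return region == "FW"


@dataclass
class LiabilityHit:
    motif: str
    chain: str
    positions: list[Pos]
    residues: str
    region: str | None = None
    max_rel_asa: float | None = None
    exposed: bool | None = None

    def to_dict(self) -> dict:
        return {"motif": self.motif, "chain": self.chain,
                "positions": [f"{p[0]}{p[1]}" for p in self.positions],
                "residues": self.residues, "region": self.region,
                "max_rel_asa": None if self.max_rel_asa is None
                else round(self.max_rel_asa, 1),
                "exposed": self.exposed}


def load_motif_table(path=None) -> list[LiabilityMotif]:
    if path is None:
        path = importlib.resources.files("fvforge.data") / "liability_motifs.tsv"
    motifs = []
    text = path.read_text() if hasattr(path, "read_text") else open(path).read()
    for line in text.splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        name, kind, pattern, regions, note = line.split("\t")
        motifs.append(LiabilityMotif(name, kind, pattern, regions, note))
    return motifs


def _load_max_asa() -> dict[str, float]:
    path = importlib.resources.files("fvforge.data") / "max_asa.tsv"
    out = {}
    for line in path.read_text().splitlines():
        if not line.strip() or line.startswith("#"):
            continue
        aa, v = line.split("\t")
        out[aa] = float(v)
    return out


_MAX_ASA = _load_max_asa()


def scan_motifs(fv: FvStructure, motifs: list[LiabilityMotif] | None = None,
                x_not_proline: bool = False) -> list[LiabilityHit]:
    """All motif matches within their applicable regions (exposure unset).

    Overlapping matches are allowed; each match is reported once per start
    position.  ``x_not_proline`` restricts the N-glycosylation sequon's X.
    """
    motifs = motifs if motifs is not None else load_motif_table()
    hits = []
    for ct in fv.chains:
        residues = sorted(fv.domain(ct), key=lambda r: pos_key(r.position))
        seq = "".join(r.aa for r in residues)
        for motif in motifs:
            if motif.kind == "regex":
                pattern = motif.pattern
                if x_not_proline and motif.name == "n_glycosylation":
                    pattern = pattern.replace("N.", "N[^P]", 1)
                rx = re.compile(pattern)
                for i in range(len(seq)):
                    m = rx.match(seq, i)
                    if not m or not motif.applies_to(residues[i].region):
                        continue
                    span = residues[i:m.end()]
                    hits.append(LiabilityHit(motif.name, ct,
                                             [r.position for r in span],
                                             m.group(0), residues[i].region))
            elif motif.kind == "unpaired_cys":
                for r in residues:
                    if r.aa == "C" and r.position[0] not in CANONICAL_CYS_POSITIONS \
                            and motif.applies_to(r.region):
                        hits.append(LiabilityHit(motif.name, ct, [r.position],
                                                 "C", r.region))
            elif motif.kind == "nterm":
                first = residues[0]
                if first.aa in motif.pattern and motif.applies_to(first.region):
                    hits.append(LiabilityHit(motif.name, ct, [first.position],
                                             first.aa, first.region))
            else:
                raise LiabilityError(f"unknown motif kind {motif.kind!r}")
    return hits


def relative_asa(fv: FvStructure, probe_radius: float = 1.4,
                 n_points: int = 196) -> dict[tuple[str, Pos], float]:
    """Per-residue relative accessible surface area (%) via Shrake-Rupley.

    Absolute ASA divided by the residue type's maximum-ASA reference, x100.
    Values can exceed 100% for unusually extended conformations.
    """
    if all(not r.side_chain_atoms() for ct in fv.chains for r in fv.domain(ct)):
        warnings.warn(f"{fv.name}: no side-chain atoms; relative ASA computed "
                      "from backbone only")
    for ct in fv.chains:
        for r in fv.domain(ct):
            if r.aa == "X":
                raise LiabilityError(
                    f"{ct}{r.position[0]}: unknown residue type, no max-ASA reference")
    pdb_text = write_structure(fv)
    parser = PDBParser(QUIET=True)
    structure = parser.get_structure(fv.name or "model", io.StringIO(pdb_text))
    ShrakeRupley(probe_radius=probe_radius, n_points=n_points).compute(
        structure, level="R")
    out = {}
    for ct in fv.chains:
        bio_chain = structure[0][ct]
        for r in fv.domain(ct):
            res_id = (" ", r.position[0], r.position[1] or " ")
            sasa = float(bio_chain[res_id].sasa)
            out[(ct, r.position)] = 100.0 * sasa / _MAX_ASA[r.aa]
    return out


def flag_exposure(hits: list[LiabilityHit],
                  rel_asa: dict[tuple[str, Pos], float],
                  threshold: float = DEFAULT_EXPOSURE_THRESHOLD
                  ) -> list[LiabilityHit]:
    """Set each hit's exposure flag: exposed iff max relative ASA over the span
    is strictly greater than the threshold."""
    for hit in hits:
        values = [rel_asa[(hit.chain, p)] for p in hit.positions
                  if (hit.chain, p) in rel_asa]
        hit.max_rel_asa = max(values) if values else 0.0
        hit.exposed = hit.max_rel_asa > threshold
    return hits


def hits_to_json(hits: list[LiabilityHit]) -> str:
    return json.dumps([h.to_dict() for h in hits], indent=1)
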