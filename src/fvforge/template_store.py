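"""Framework-template and loop-fragment libraries.

The template store indexes resolution-filtered structures for framework
selection (single "global" template when one record reaches the identity
threshold on both chains; otherwise per-chain "hybrid" donors, with the
best global candidate providing the inter-domain orientation).  Fragment
stores hold CDR loop fragments with flanking framework anchors: six
CDR-specific databases (one per loop) built from the redundant set so
sequence-identical loops keep their distinct conformations, plus an
Fv-specific fallback database of all contiguous backbone fragments indexed
by length.  The all-vs-all framework superimposition table produced here
feeds confidence calibration.
"""

from __future__ import annotations

import json
import pathlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .fv_model import (REGION_FW, CdrDefinitionTable, FvSequence, FvStructure,
                       assign_regions, framework_sequence_identity, pos_key,
                       read_structure, write_structure)
from .geometry import _paired_backbone, framework_rmsd, kabsch_superpose

DEFAULT_RESOLUTION_CUTOFF = 2.5
DEFAULT_N_ANCHOR = 5
CDR_TYPES = ("L1", "L2", "L3", "H1", "H2", "H3")


class TemplateStoreError(ValueError):
    pass


@dataclass
class TemplateRecord:
    id: str
    resolution: float
    fv: FvStructure

    @property
    def chains(self) -> list[str]:
        return self.fv.chains

    def fw_map(self, chain_type: str) -> dict:
        return {r.position: r.aa for r in self.fv.domain(chain_type)
                if r.region == REGION_FW}


@dataclass
class TemplateSelection:
    mode: str                       # 'global' | 'hybrid'
    vh_id: str | None = None
    vh_identity: float | None = None
    vl_id: str | None = None
    vl_identity: float | None = None
    orientation_id: str | None = None

    def __post_init__(self):
        if self.mode == "global":
            ids = {i for i in (self.vh_id, self.vl_id) if i is not None}
            if len(ids) != 1 or self.orientation_id not in ids:
                raise TemplateStoreError(
                    "global selection must use a single record for both chains "
                    "and the orientation")

    def donor(self, chain_type: str) -> str:
        return self.vh_id if chain_type == "H" else self.vl_id


class TemplateStore:
    """Resolution-filtered, chain-indexed framework template library."""

    def __init__(self, records: list[TemplateRecord],
                 resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF):
        self.resolution_cutoff = resolution_cutoff
        self.records = sorted(records, key=lambda r: r.id)
        if not self.records:
            raise TemplateStoreError("template store is empty after filtering")

    def __len__(self) -> int:
        return len(self.records)

    def __getitem__(self, record_id: str) -> TemplateRecord:
        for r in self.records:
            if r.id == record_id:
                return r
        raise KeyError(record_id)

    def with_chain(self, chain_type: str) -> list[TemplateRecord]:
        return [r for r in self.records if r.fv.has_chain(chain_type)]

    def save(self, out_dir) -> None:
        out = pathlib.Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        lines = ["id\tresolution\tchains"]
        for r in self.records:
            write_structure(r.fv, out / f"{r.id}.pdb")
            lines.append(f"{r.id}\t{r.resolution}\t{''.join(r.chains)}")
        (out / "templates.tsv").write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, in_dir, defs: CdrDefinitionTable,
             resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF) -> "TemplateStore":
        in_dir = pathlib.Path(in_dir)
        df = pd.read_csv(in_dir / "templates.tsv", sep="\t")
        structures = []
        for _i, row in df.iterrows():
            chain_map = {c: c for c in str(row["chains"])}
            fv = read_structure(in_dir / f"{row['id']}.pdb", chain_map,
                                name=str(row["id"]))
            structures.append((assign_regions(fv, defs), float(row["resolution"])))
        return build_template_store(structures, resolution_cutoff)


def build_template_store(structures: list[tuple[FvStructure, float]],
                         resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF
                         ) -> TemplateStore:
    """Index numbered, region-assigned structures passing the resolution cutoff."""
    records = [TemplateRecord(fv.name, res, fv) for fv, res in structures
               if res <= resolution_cutoff]
    return TemplateStore(records, resolution_cutoff)


@dataclass
class LoopFragment:
    """A CDR (or arbitrary contiguous) backbone fragment with anchor geometry."""

    source_id: str
    cdr_type: str                   # 'L1'..'H3' or 'fv'
    length: int
    sequence: str
    loop_bb: np.ndarray             # (length, 4, 3) backbone N,CA,C,O
    n_anchor_bb: np.ndarray         # (n_anchor, 4, 3)
    c_anchor_bb: np.ndarray
    resolution: float

    def __post_init__(self):
        for arr in (self.loop_bb, self.n_anchor_bb, self.c_anchor_bb):
            if not np.all(np.isfinite(arr)):
                raise TemplateStoreError("fragment coordinates must be finite")
        if len(self.n_anchor_bb) != len(self.c_anchor_bb):
            raise TemplateStoreError("anchor residue counts must match")

    @property
    def n_anchor(self) -> int:
        return len(self.n_anchor_bb)

    @property
    def span(self) -> float:
        """CA-CA distance between the innermost anchor residues (Å)."""
        return float(np.linalg.norm(self.n_anchor_bb[-1, 1] - self.c_anchor_bb[0, 1]))

    def anchor_coords(self) -> np.ndarray:
        """Both anchors as one (2 * n_anchor * 4, 3) rigid body."""
        return np.vstack([self.n_anchor_bb.reshape(-1, 3),
                          self.c_anchor_bb.reshape(-1, 3)])


class FragmentStore:
    def __init__(self, fragments: list[LoopFragment], kind: str):
        self.kind = kind
        self.fragments = fragments
        self._by_length: dict[int, list[LoopFragment]] = {}
        for f in fragments:
            self._by_length.setdefault(f.length, []).append(f)

    def __len__(self) -> int:
        return len(self.fragments)

    def of_length(self, length: int) -> list[LoopFragment]:
        return self._by_length.get(length, [])

    @property
    def lengths(self) -> list[int]:
        return sorted(self._by_length)


def _domain_backbone(fv: FvStructure, chain_type: str):
    """(residues, (n,4,3) backbone array) for residues with complete backbones."""
    residues = [r for r in fv.domain(chain_type) if r.has_backbone()]
    if not residues:
        return [], np.zeros((0, 4, 3))
    return residues, np.array([r.backbone_coords() for r in residues])


def _cdr_fragment(fv: FvStructure, chain_type: str, cdr_index: int,
                  n_anchor: int, resolution: float) -> LoopFragment | None:
    residues, bb = _domain_backbone(fv, chain_type)
    idx = [i for i, r in enumerate(residues) if r.region == f"CDR{cdr_index}"]
    if not idx:
        return None
    first, last = idx[0], idx[-1]
    if first - n_anchor < 0 or last + n_anchor >= len(residues):
        warnings.warn(f"{fv.name}: CDR{chain_type}{cdr_index} too close to a "
                      f"terminus for {n_anchor}-residue anchors; fragment skipped")
        return None
    return LoopFragment(
        source_id=fv.name, cdr_type=f"{chain_type}{cdr_index}",
        length=last - first + 1,
        sequence="".join(r.aa for r in residues[first:last + 1]),
        loop_bb=bb[first:last + 1].copy(),
        n_anchor_bb=bb[first - n_anchor:first].copy(),
        c_anchor_bb=bb[last + 1:last + 1 + n_anchor].copy(),
        resolution=resolution)


def build_fragment_stores(structures: list[tuple[FvStructure, float]],
                          n_anchor: int = DEFAULT_N_ANCHOR,
                          fv_lengths: list[int] | None = None
                          ) -> dict[str, FragmentStore]:
    """Six CDR-specific fragment stores plus the length-indexed Fv-specific store.

    Duplicate-sequence loops are retained on purpose: the redundant set is what
    captures multiple conformations of sequence-identical loops.  ``fv_lengths``
    restricts the Fv-specific store to the given fragment lengths (default:
    every CDR length observed in the input).
    """
    stores: dict[str, list[LoopFragment]] = {k: [] for k in CDR_TYPES}
    stores["fv"] = []
    for fv, resolution in structures:
        for ct in fv.chains:
            for k in (1, 2, 3):
                frag = _cdr_fragment(fv, ct, k, n_anchor, resolution)
                if frag is not None:
                    stores[f"{ct}{k}"].append(frag)
    lengths = sorted(set(fv_lengths)) if fv_lengths else sorted(
        {f.length for frags in stores.values() for f in frags})
    for fv, resolution in structures:
        for ct in fv.chains:
            residues, bb = _domain_backbone(fv, ct)
            seq = "".join(r.aa for r in residues)
            for length in lengths:
                for start in range(n_anchor, len(residues) - length - n_anchor + 1):
                    stores["fv"].append(LoopFragment(
                        source_id=fv.name, cdr_type="fv", length=length,
                        sequence=seq[start:start + length],
                        loop_bb=bb[start:start + length],
                        n_anchor_bb=bb[start - n_anchor:start],
                        c_anchor_bb=bb[start + length:start + length + n_anchor],
                        resolution=resolution))
    return {k: FragmentStore(v, k) for k, v in stores.items()}


def _as_sequence(target) -> FvSequence:
    return FvSequence.from_structure(target) if isinstance(target, FvStructure) else target


def _identity(target: FvSequence, record: TemplateRecord, chain_type: str,
              defs: CdrDefinitionTable) -> float:
    t_fw = target.fw_map(chain_type, defs)
    r_fw = record.fw_map(chain_type)
    shared = set(t_fw) & set(r_fw)
    if not shared:
        return 0.0
    return 100.0 * sum(t_fw[p] == r_fw[p] for p in shared) / len(shared)


def _is_identical(target: FvSequence, record: TemplateRecord) -> bool:
    """Full-Fv sequence identity, independent of numbering gap placement."""
    for ct in target.chains:
        if not record.fv.has_chain(ct):
            return False
        t_seq = "".join(target.chains[ct][p] for p in target.positions(ct))
        if t_seq != record.fv.sequence(ct):
            return False
    return True


def select_framework_template(target, store: TemplateStore,
                              defs: CdrDefinitionTable,
                              identity_threshold: float = 80.0,
                              exclude_identical: bool = False) -> TemplateSelection:
    """Choose framework template(s) for a target sequence.

    Global mode when the best joint record reaches ``identity_threshold`` on
    both chains (best = maximum of the minimum per-chain identity, ties broken
    by better resolution then id); otherwise hybrid with per-chain donors and
    the best global candidate as orientation source.  Single-domain targets
    select trivially in global mode.
    """
    target = _as_sequence(target)
    records = [r for r in store.records
               if not (exclude_identical and _is_identical(target, r))]
    if not records:
        raise TemplateStoreError("no templates remain after identity exclusion")
    chains = target.chains
    ids = {(r.id, ct): _identity(target, r, ct, defs)
           for r in records for ct in chains if r.fv.has_chain(ct)}

    def best(cands, score):
        return min(cands, key=lambda r: (-score(r), r.resolution, r.id), default=None)

    if len(chains) == 1:
        ct = next(iter(chains))
        cands = [r for r in records if r.fv.has_chain(ct)]
        chosen = best(cands, lambda r: ids[(r.id, ct)])
        if chosen is None:
            raise TemplateStoreError(f"no template with chain {ct}")
        identity = ids[(chosen.id, ct)]
        kw = {"vh_id": chosen.id, "vh_identity": identity} if ct == "H" else \
             {"vl_id": chosen.id, "vl_identity": identity}
        return TemplateSelection("global", orientation_id=chosen.id, **kw)

    joint = [r for r in records if r.fv.has_chain("H") and r.fv.has_chain("L")]
    best_global = best(joint, lambda r: min(ids[(r.id, "H")], ids[(r.id, "L")]))
    if best_global is not None and \
            min(ids[(best_global.id, "H")], ids[(best_global.id, "L")]) >= identity_threshold:
        return TemplateSelection(
            "global", vh_id=best_global.id, vh_identity=ids[(best_global.id, "H")],
            vl_id=best_global.id, vl_identity=ids[(best_global.id, "L")],
            orientation_id=best_global.id)
    vh = best([r for r in records if r.fv.has_chain("H")], lambda r: ids[(r.id, "H")])
    vl = best([r for r in records if r.fv.has_chain("L")], lambda r: ids[(r.id, "L")])
    if vh is None or vl is None:
        raise TemplateStoreError("hybrid selection needs donors for both chains")
    if best_global is None:
        raise TemplateStoreError("no two-chain record available as orientation source")
    return TemplateSelection(
        "hybrid", vh_id=vh.id, vh_identity=ids[(vh.id, "H")],
        vl_id=vl.id, vl_identity=ids[(vl.id, "L")],
        orientation_id=best_global.id)


def _fv_fw_identity(a: FvStructure, b: FvStructure) -> float:
    total = same = 0
    for ct in ("H", "L"):
        if not (a.has_chain(ct) and b.has_chain(ct)):
            continue
        amap = {r.position: r.aa for r in a.domain(ct) if r.region == REGION_FW}
        bmap = {r.position: r.aa for r in b.domain(ct) if r.region == REGION_FW}
        shared = set(amap) & set(bmap)
        total += len(shared)
        same += sum(amap[p] == bmap[p] for p in shared)
    if total == 0:
        raise TemplateStoreError("no shared framework positions")
    return 100.0 * same / total


def _fv_fw_rmsd(a: FvStructure, b: FvStructure) -> float:
    blocks = []
    for ct in ("H", "L"):
        if a.has_chain(ct) and b.has_chain(ct):
            pa, pb = _paired_backbone(a, b, ct, REGION_FW)
            if len(pa):
                blocks.append((pa, pb))
    if not blocks:
        raise TemplateStoreError("no shared framework atoms")
    _tf, rmsd = kabsch_superpose(np.vstack([x for x, _ in blocks]),
                                 np.vstack([y for _, y in blocks]))
    return rmsd


def pairwise_superimposition_table(structures, kind: str = "fv") -> pd.DataFrame:
    """All-vs-all framework identity and RMSD for unordered structure pairs.

    ``kind``: 'fv' superimposes both chains' frameworks jointly; 'vh'/'vl'
    one chain.  Rows: id_a, id_b, kind, identity (%), rmsd (Å).
    """
    if kind not in ("fv", "vh", "vl"):
        raise TemplateStoreError(f"unknown comparison kind {kind!r}")
    fvs = [s[0] if isinstance(s, tuple) else s for s in structures]
    ct = {"vh": "H", "vl": "L"}.get(kind)
    if ct is not None:
        fvs = [f for f in fvs if f.has_chain(ct)]
    else:
        fvs = [f for f in fvs if f.is_paired()]
    rows = []
    for i in range(len(fvs)):
        for j in range(i + 1, len(fvs)):
            a, b = fvs[i], fvs[j]
            if kind == "fv":
                identity, rmsd = _fv_fw_identity(a, b), _fv_fw_rmsd(a, b)
            else:
                identity = framework_sequence_identity(a, b, ct)
                rmsd = framework_rmsd(a, b, ct).rmsd
            rows.append({"id_a": a.name, "id_b": b.name, "kind": kind,
                         "identity": identity, "rmsd": rmsd})
    return pd.DataFrame(rows, columns=["id_a", "id_b", "kind", "identity", "rmsd"])


def deduplicate(structures: list[tuple[FvStructure, float]],
                identity_cutoff: float = 90.0) -> list[tuple[FvStructure, float]]:
    """Greedy framework-identity deduplication (fixture prep, not pipeline logic)."""
    kept: list[tuple[FvStructure, float]] = []
    for fv, res in structures:
        if any(_fv_fw_identity(fv, k) > identity_cutoff for k, _r in kept):
            continue
        kept.append((fv, res))
    return kept
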