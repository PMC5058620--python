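"""Fragment-database CDR loop prediction.

Candidate loop fragments of the target length are filtered on anchor CA-CA
span mismatch and a sequence-compatibility substitution score, then ranked by
anchor RMSD after jointly superimposing both fragment anchors (as one rigid
body) onto the model's anchors — the decoy with the lowest anchor RMSD wins
even when another passing decoy scores higher on sequence.  Loops are modeled
in a fixed order (CDRL2, CDRH2, CDRL1, CDRH1, CDRL3, CDRH3; heavy-only order
conserved: H2, H1, H3), each graft updating the model before the next search.

When the CDR-specific database yields no decoy, the search cascades to the
Fv-specific database; then to the most sequence-similar length-matched loop
(grafted ignoring filters); and finally raises a structured ab-initio signal
carrying the closest unequal-length fragment as a hook for external modelers.

The substitution score is a plain BLOSUM62 sum — a stand-in for
environment-specific substitution scoring, kept pluggable; its default
acceptance threshold (25) is of the magnitude of published scores for
accepted decoys.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from .fv_model import FvSequence, FvStructure, AtomRecord, NumberedResidue, pos_key
from .geometry import RigidTransform, kabsch_superpose
from .template_store import (DEFAULT_RESOLUTION_CUTOFF, FragmentStore,
                             LoopFragment)

DEFAULT_SPAN_TOLERANCE = 0.8     # Å
DEFAULT_SCORE_THRESHOLD = 25
LOOP_ORDER = (("L", 2), ("H", 2), ("L", 1), ("H", 1), ("L", 3), ("H", 3))

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


class GraftError(ValueError):
    pass


class AbInitioRequired(Exception):
    """No length-matched fragment exists; external loop building is needed.

    Carries the most sequence-similar unequal-length fragment (or None when
    the stores are empty) as a starting template for an external modeler.
    """

    def __init__(self, cdr: str, closest: LoopFragment | None):
        self.cdr = cdr
        self.closest = closest
        super().__init__(f"{cdr}: no length-matched fragment; ab initio "
                         "loop building required")


@dataclass
class AnchorPair:
    """Model-side anchor geometry flanking one CDR."""

    n_anchor_bb: np.ndarray         # (n_anchor, 4, 3)
    c_anchor_bb: np.ndarray

    def __post_init__(self):
        self.n_anchor_bb = np.asarray(self.n_anchor_bb, float)
        self.c_anchor_bb = np.asarray(self.c_anchor_bb, float)
        if self.span <= 0:
            raise GraftError("anchor span must be positive")

    @property
    def span(self) -> float:
        return float(np.linalg.norm(self.n_anchor_bb[-1, 1] - self.c_anchor_bb[0, 1]))

    def coords(self) -> np.ndarray:
        return np.vstack([self.n_anchor_bb.reshape(-1, 3),
                          self.c_anchor_bb.reshape(-1, 3)])


@dataclass
class LoopDecoy:
    fragment: LoopFragment
    score: int
    anchor_rmsd: float
    span_mismatch: float
    transform: RigidTransform
    stage: str = "cdr-db"

    def __post_init__(self):
        if self.anchor_rmsd < 0:
            raise GraftError("anchor RMSD must be non-negative")

    @property
    def rank_key(self):
        # total order: anchor RMSD, then higher score, then resolution, then id
        return (self.anchor_rmsd, -self.score, self.fragment.resolution,
                self.fragment.source_id)


def substitution_score(target_seq: str, fragment_seq: str) -> int:
    """BLOSUM62 sum over aligned positions of two equal-length loop sequences."""
    if len(target_seq) != len(fragment_seq):
        raise GraftError(f"sequence length mismatch: {len(target_seq)} vs "
                         f"{len(fragment_seq)}")
    return int(sum(_BLOSUM62[a, b] for a, b in zip(target_seq, fragment_seq)))


def model_anchors(model: FvStructure, chain_type: str, cdr_index: int,
                  n_anchor: int) -> AnchorPair:
    """Extract the n_anchor framework residues flanking a CDR of the model."""
    residues = [r for r in model.domain(chain_type) if r.has_backbone()]
    idx = [i for i, r in enumerate(residues) if r.region == f"CDR{cdr_index}"]
    if not idx:
        raise GraftError(f"model has no CDR{chain_type}{cdr_index} residues")
    first, last = idx[0], idx[-1]
    if first - n_anchor < 0 or last + n_anchor >= len(residues):
        raise GraftError(f"CDR{chain_type}{cdr_index}: insufficient anchor residues")
    bb = np.array([r.backbone_coords() for r in residues])
    return AnchorPair(bb[first - n_anchor:first], bb[last + 1:last + 1 + n_anchor])


def candidate_decoys(target_seq: str, anchors: AnchorPair, store: FragmentStore,
                     span_tolerance: float = DEFAULT_SPAN_TOLERANCE,
                     score_threshold: int = DEFAULT_SCORE_THRESHOLD,
                     exclude_ids: set | tuple = (),
                     apply_filters: bool = True) -> list[LoopDecoy]:
    """Filter and rank length-matched fragments against the model anchors.

    Keeps fragments with |span mismatch| <= tolerance and substitution score
    >= threshold (both skipped with ``apply_filters=False``), superimposes
    each fragment's anchors jointly onto the model anchors, and returns decoys
    ranked ascending by anchor RMSD.  An empty store yields an empty list.
    """
    anchor_ref = anchors.coords()
    decoys = []
    for frag in store.of_length(len(target_seq)):
        if frag.source_id in exclude_ids:
            continue
        span_mismatch = abs(frag.span - anchors.span)
        score = substitution_score(target_seq, frag.sequence)
        if apply_filters and (span_mismatch > span_tolerance or
                              score < score_threshold):
            continue
        tf, anchor_rmsd = kabsch_superpose(frag.anchor_coords(), anchor_ref)
        decoys.append(LoopDecoy(frag, score, anchor_rmsd, span_mismatch, tf))
    return sorted(decoys, key=lambda d: d.rank_key)


def graft_loop(model: FvStructure, decoy: LoopDecoy, chain_type: str,
               cdr_index: int, target_loop: list[tuple[tuple, str]],
               max_junction_gap: float = 4.5) -> FvStructure:
    """Replace the model's CDR backbone with the decoy loop (anchors fixed).

    The fragment's loop backbone is mapped through the joint-anchor transform;
    residue identities come from the target sequence (side chains are handled
    by the side-chain stage).  Raises :class:`GraftError` when a junction or
    intra-loop CA-CA distance exceeds ``max_junction_gap``.
    """
    region = f"CDR{cdr_index}"
    if decoy.fragment.length != len(target_loop):
        raise GraftError("decoy length does not match target CDR length")
    loop_bb = decoy.transform.apply(
        decoy.fragment.loop_bb.reshape(-1, 3)).reshape(-1, 4, 3)

    out = model.copy()
    domain = out.domain(chain_type)
    kept = [r for r in domain if r.region != region]
    new_residues = []
    for (pos, aa), bb in zip(target_loop, loop_bb):
        atoms = [AtomRecord(n, n[0], bb[i]) for i, n in
                 enumerate(("N", "CA", "C", "O"))]
        new_residues.append(NumberedResidue(chain_type, pos, aa, atoms, region))
    merged = sorted(kept + new_residues, key=lambda r: pos_key(r.position))
    if chain_type == "H":
        out.heavy = merged
    else:
        out.light = merged

    idx = [i for i, r in enumerate(merged) if r.region == region]
    first, last = idx[0], idx[-1]
    junctions = []
    if first > 0:
        junctions.append(("N-junction", merged[first - 1], merged[first]))
    if last + 1 < len(merged):
        junctions.append(("C-junction", merged[last], merged[last + 1]))
    for label, a, b in junctions:
        if not (a.has_backbone() and b.has_backbone()):
            continue
        d = float(np.linalg.norm(a.atom("CA").coord - b.atom("CA").coord))
        if d > max_junction_gap:
            raise GraftError(
                f"CDR{chain_type}{cdr_index} {label} backbone break: CA-CA "
                f"{d:.2f} Å between {a.position[0]}{a.position[1]} and "
                f"{b.position[0]}{b.position[1]}")
    # intra-loop steps are the fragment's own geometry (rigidly transformed):
    # an oversized one reflects the source fragment, not a graft failure
    for i in idx[:-1]:
        a, b = merged[i], merged[i + 1]
        d = float(np.linalg.norm(a.atom("CA").coord - b.atom("CA").coord))
        if d > max_junction_gap:
            warnings.warn(f"CDR{chain_type}{cdr_index}: intra-loop CA-CA "
                          f"{d:.2f} Å inherited from fragment "
                          f"{decoy.fragment.source_id}")
    return out


def _most_similar_any_length(target_seq: str, stores: list[FragmentStore],
                             exclude_ids) -> LoopFragment | None:
    """Best global-alignment BLOSUM62 match among unequal-length fragments."""
    aligner = Align.PairwiseAligner()
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -10.0
    aligner.extend_gap_score = -0.5
    best, best_score = None, None
    for store in stores:
        for frag in store.fragments:
            if frag.source_id in exclude_ids or frag.length == len(target_seq):
                continue
            score = aligner.score(target_seq, frag.sequence)
            if best_score is None or score > best_score:
                best, best_score = frag, score
    return best


def model_cdr(model: FvStructure, target: FvSequence, chain_type: str,
              cdr_index: int, stores: dict[str, FragmentStore], defs,
              n_anchor: int = 5,
              span_tolerance: float = DEFAULT_SPAN_TOLERANCE,
              score_threshold: int = DEFAULT_SCORE_THRESHOLD,
              resolution_cutoff: float = DEFAULT_RESOLUTION_CUTOFF,
              exclude_ids: set | tuple = ()
              ) -> tuple[FvStructure, str, LoopDecoy | None]:
    """Model one CDR through the three-stage fallback cascade.

    Stages: CDR-specific database -> Fv-specific database -> most
    sequence-similar length-matched loop (resolution-filtered, grafted
    ignoring filters) -> :class:`AbInitioRequired`.
    """
    cdr_name = f"{chain_type}{cdr_index}"
    target_loop = target.cdr_segment(chain_type, cdr_index, defs)
    if not target_loop:
        raise GraftError(f"target has no CDR{cdr_name} positions")
    target_seq = "".join(aa for _p, aa in target_loop)
    anchors = model_anchors(model, chain_type, cdr_index, n_anchor)

    for stage, store_key in (("cdr-db", cdr_name), ("fv-db", "fv")):
        store = stores.get(store_key)
        if store is None:
            continue
        decoys = candidate_decoys(target_seq, anchors, store, span_tolerance,
                                  score_threshold, exclude_ids)
        if decoys:
            best = decoys[0]
            best.stage = stage
            return graft_loop(model, best, chain_type, cdr_index,
                              target_loop), stage, best

    # sequence-similar fallback: length-matched, resolution-filtered, no filters
    pool = []
    for key in (cdr_name, "fv"):
        store = stores.get(key)
        if store is not None:
            pool.extend(f for f in store.of_length(len(target_seq))
                        if f.resolution <= resolution_cutoff
                        and f.source_id not in exclude_ids)
    if pool:
        anchor_ref = anchors.coords()
        scored = []
        for frag in pool:
            tf, anchor_rmsd = kabsch_superpose(frag.anchor_coords(), anchor_ref)
            score = substitution_score(target_seq, frag.sequence)
            scored.append(LoopDecoy(frag, score, anchor_rmsd,
                                    abs(frag.span - anchors.span), tf,
                                    stage="seq-similar"))
        best = min(scored, key=lambda d: (-d.score, d.anchor_rmsd,
                                          d.fragment.resolution,
                                          d.fragment.source_id))
        return graft_loop(model, best, chain_type, cdr_index,
                          target_loop), "seq-similar", best

    closest = _most_similar_any_length(
        target_seq, [s for k, s in stores.items() if k in (cdr_name, "fv")],
        exclude_ids)
    raise AbInitioRequired(f"CDR{cdr_name}", closest)


def model_all_cdrs(model: FvStructure, target: FvSequence,
                   stores: dict[str, FragmentStore], defs,
                   **kwargs) -> tuple[FvStructure, list[tuple[str, str, LoopDecoy | None]]]:
    """Model every CDR of the target in the fixed order, updating anchors as it goes.

    Returns the final model and, per loop in modeling order, (cdr name, stage,
    decoy).  Paired targets follow L2, H2, L1, H1, L3, H3; single-domain
    targets keep the order restricted to their chain.
    """
    provenance = []
    for chain_type, cdr_index in LOOP_ORDER:
        if chain_type not in target.chains:
            continue
        model, stage, decoy = model_cdr(model, target, chain_type, cdr_index,
                                        stores, defs, **kwargs)
        provenance.append((f"{chain_type}{cdr_index}", stage, decoy))
    return model, provenance
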