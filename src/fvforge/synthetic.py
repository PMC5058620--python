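"""Synthetic antibody fixtures with known ground truth.

Generates idealized Fv structures (regular-strand serpentine backbones with
chemically complete, rotamer-library side chains), families of related
structures whose pairwise framework identities bracket the template-selection
threshold and whose coordinate deviations grow with sequence distance, and
synthetic calibration tables drawn from known per-bin RMSD distributions.

These are geometric/statistical stand-ins, not physically folded antibodies:
every pipeline contract under test is about numbering, superposition,
fragment search and counting statistics, none of which require an energy
model.  Generation is deterministic per seed, and ground-truth parameters are
serialized next to any data written to disk.
"""

from __future__ import annotations

import json
import pathlib
from dataclasses import dataclass, field, asdict

import numpy as np

from . import confidence as _confidence
from .chem import AMINO_ACIDS, build_backbone, build_side_chain
from .fv_model import (CANONICAL_CYS_POSITIONS, AtomRecord, CdrDefinitionTable,
                       FvStructure, NumberedResidue, assign_regions,
                       consensus_sequence, write_structure)
from .side_chains import RotamerLibrary

_LAST_POSITION = 125
_STRAND_PHI_PSI = (-139.0, 135.0)
_TURN_PHI_PSI = (-65.0, -35.0)
_LOOP_PHI_PSI = (-80.0, -10.0)

DEFAULT_CDR_LENGTHS = {("H", 1): 10, ("H", 2): 8, ("H", 3): 12,
                       ("L", 1): 11, ("L", 2): 8, ("L", 3): 9}


@dataclass
class FixtureSpec:
    """Generation parameters for a synthetic template family."""

    n_structures: int = 16
    cdr_lengths: dict = field(default_factory=lambda: dict(DEFAULT_CDR_LENGTHS))
    mutation_rate: float = 0.35        # max framework mutation fraction in the family
    cdr_mutation_rate: float = 0.25    # CDR mutation fraction at max sequence distance
    noise_sigma: float = 1.0           # Å of per-atom noise per unit mutation fraction
    noise_floor: float = 0.05          # baseline noise fraction (experimental scatter)
    orientation_jitter_deg: float = 4.0
    resolution_range: tuple = (1.5, 2.4)
    seed: int = 0

    def __post_init__(self):
        if self.n_structures <= 0:
            raise ValueError("n_structures must be positive")
        if self.noise_sigma < 0 or self.noise_floor < 0:
            raise ValueError("noise parameters must be non-negative")
        if any(n <= 0 for n in self.cdr_lengths.values()):
            raise ValueError("CDR lengths must be positive")


def domain_layout(chain_type: str, cdr_lengths: dict,
                  defs: CdrDefinitionTable) -> list[tuple[tuple[int, str], str]]:
    """Ordered (position, region) pairs for one synthetic domain.

    Framework segments are the complement of the CDR intervals over positions
    1..125; each CDR occupies the leading ``cdr_lengths`` positions of its
    interval.
    """
    intervals = [defs.interval(chain_type, k) for k in (1, 2, 3)]
    out: list[tuple[tuple[int, str], str]] = []
    cursor = 1
    for k, (start, end) in enumerate(intervals, start=1):
        for p in range(cursor, start):
            out.append(((p, ""), "FW"))
        length = cdr_lengths[(chain_type, k)]
        if length > end - start + 1:
            raise ValueError(f"CDR{chain_type}{k} length {length} exceeds interval "
                             f"{start}-{end}")
        for p in range(start, start + length):
            out.append(((p, ""), f"CDR{k}"))
        cursor = end + 1
    for p in range(cursor, _LAST_POSITION + 1):
        out.append(((p, ""), "FW"))
    return out


def base_sequence(chain_type: str, cdr_lengths: dict,
                  defs: CdrDefinitionTable) -> dict[tuple[int, str], str]:
    """Consensus-derived residue per layout position."""
    cons = consensus_sequence(chain_type)
    return {pos: cons[pos[0] - 1] for pos, _region in
            domain_layout(chain_type, cdr_lengths, defs)}


def _phi_psi_for(layout) -> list[tuple[float, float]]:
    out = []
    strand_i = 0
    for _pos, region in layout:
        if region != "FW":
            out.append(_LOOP_PHI_PSI)
        else:
            out.append(_STRAND_PHI_PSI if strand_i % 16 < 12 else _TURN_PHI_PSI)
            strand_i += 1
    return out


def _smooth_displacement_field(n_res: int, sigma: float,
                               rng: np.random.Generator,
                               n_modes: int = 6) -> np.ndarray:
    """(n_res, 3) displacement field from random low-frequency modes.

    Per-residue RMS displacement is scaled to ``sigma``; adjacent residues
    move almost together, mimicking collective structural deformation.
    """
    t = np.linspace(0.0, 1.0, n_res)[:, None]
    field = np.zeros((n_res, 3))
    for _ in range(n_modes):
        freq = rng.uniform(0.5, 3.0)
        phase = rng.uniform(0.0, 2 * np.pi, 3)
        amp = rng.normal(0.0, 1.0, 3)
        field += amp * np.sin(2 * np.pi * freq * t + phase)
    rms = np.sqrt(np.mean(np.sum(field ** 2, axis=1)) / 3.0)
    return field * (sigma / max(rms, 1e-9))


def _random_rotation(rng: np.random.Generator, max_angle_deg: float) -> np.ndarray:
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.deg2rad(rng.normal(0.0, max_angle_deg / 2.0)) if max_angle_deg > 0 else 0.0
    k = np.array([[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]],
                  [-axis[1], axis[0], 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _build_domain(chain_type: str, seq: dict, layout, library: RotamerLibrary,
                  rng: np.random.Generator | None,
                  rotamer_choice: str = "top") -> list[NumberedResidue]:
    phi_psi = _phi_psi_for(layout)
    backbone = build_backbone(phi_psi)
    residues = []
    for (pos, region), bb in zip(layout, backbone):
        aa = seq[pos]
        atoms = [AtomRecord(n, n[0], bb[n]) for n in ("N", "CA", "C", "O")]
        rots = library(aa)
        if rots:
            if rotamer_choice == "random" and rng is not None:
                probs = np.array([p for _c, p in rots])
                chis = rots[rng.choice(len(rots), p=probs / probs.sum())][0]
            else:
                chis = rots[0][0]
        else:
            chis = ()
        for name, element, coord in build_side_chain(aa, bb, chis):
            atoms.append(AtomRecord(name, element, coord))
        residues.append(NumberedResidue(chain_type, pos, aa, atoms, region))
    return residues


def make_idealized_fv(cdr_lengths: dict | None = None, chains: str = "HL",
                      defs: CdrDefinitionTable | None = None,
                      sequences: dict | None = None, name: str = "ideal",
                      seed: int | None = None,
                      rotamer_choice: str = "top",
                      noise_sigma: float = 0.0,
                      orientation_jitter_deg: float = 0.0) -> FvStructure:
    """One idealized, numbered, region-assigned Fv (or single-domain) structure.

    Deterministic per seed.  ``sequences`` may override the consensus-derived
    residue per position ({chain: {pos: aa}}).
    """
    cdr_lengths = cdr_lengths or dict(DEFAULT_CDR_LENGTHS)
    defs = defs or CdrDefinitionTable.load("north")
    library = RotamerLibrary.load()
    rng = np.random.default_rng(seed) if seed is not None else None
    domains = {}
    for ct in chains:
        layout = domain_layout(ct, cdr_lengths, defs)
        seq = dict(base_sequence(ct, cdr_lengths, defs))
        if sequences and ct in sequences:
            seq.update(sequences[ct])
        domains[ct] = _build_domain(ct, seq, layout, library, rng, rotamer_choice)
    if "L" in domains:
        # place VL beside VH with an antiparallel flip plus optional jitter
        flip = np.diag([-1.0, 1.0, -1.0])
        jitter = (_random_rotation(rng, orientation_jitter_deg)
                  if rng is not None and orientation_jitter_deg > 0 else np.eye(3))
        rot = jitter @ flip
        offset = np.array([40.0, 8.0, 25.0])
        for r in domains["L"]:
            for a in r.atoms:
                a.coord = rot @ a.coord + offset
    if noise_sigma > 0 and rng is not None:
        # smooth low-frequency deformation per domain: neighbouring residues
        # move together, so local bond geometry stays intact while global
        # deviation reaches the requested per-atom RMS
        for dom in domains.values():
            field = _smooth_displacement_field(len(dom), noise_sigma, rng)
            for r, shift in zip(dom, field):
                local = rng.normal(0.0, 0.02, 3)
                for a in r.atoms:
                    a.coord = a.coord + shift + local
    fv = FvStructure(heavy=domains.get("H"), light=domains.get("L"),
                     name=name, scheme="consensus")
    return assign_regions(fv, defs)


def _mutate(seq: dict, n_mut: int, rng: np.random.Generator,
            protected: set) -> dict:
    alphabet = [a for a in AMINO_ACIDS if a != "C"]
    out = dict(seq)
    candidates = [p for p in out if p[0] not in protected]
    if n_mut <= 0 or not candidates:
        return out
    idx = rng.choice(len(candidates), size=min(n_mut, len(candidates)), replace=False)
    for i in np.atleast_1d(idx):
        pos = candidates[int(i)]
        choices = [a for a in alphabet if a != out[pos]]
        out[pos] = choices[int(rng.integers(len(choices)))]
    return out


def make_template_family(spec: FixtureSpec | None = None,
                         chains: str = "HL",
                         defs: CdrDefinitionTable | None = None
                         ) -> tuple[list[tuple[FvStructure, float]], dict]:
    """Family of related synthetic structures with recorded ground truth.

    Member mutation fractions are spaced from 0 to ``spec.mutation_rate`` so
    pairwise framework identities bracket the 80% template threshold; per-atom
    coordinate noise grows linearly with each member's mutation fraction
    (sigma = noise_sigma * (noise_floor + fraction)), so pairwise RMSD grows
    stochastically with sequence distance.  Returns (structure, resolution)
    pairs and the ground-truth parameter record.
    """
    spec = spec or FixtureSpec()
    defs = defs or CdrDefinitionTable.load("north")
    rng = np.random.default_rng(spec.seed)
    protected = set(CANONICAL_CYS_POSITIONS)
    base = {ct: base_sequence(ct, spec.cdr_lengths, defs) for ct in chains}
    fracs = (np.linspace(0.0, spec.mutation_rate, spec.n_structures)
             if spec.n_structures > 1 else np.array([0.0]))
    members, truth_members = [], []
    for i, frac in enumerate(fracs):
        seqs = {}
        for ct in chains:
            layout = domain_layout(ct, spec.cdr_lengths, defs)
            fw_n = sum(1 for _p, reg in layout if reg == "FW")
            cdr_n = len(layout) - fw_n
            seq = _mutate(base[ct], round(frac * fw_n), rng, protected | {
                p[0] for p, reg in layout if reg != "FW"})
            seq = _mutate(seq, round(frac * spec.cdr_mutation_rate * cdr_n), rng,
                          protected | {p[0] for p, reg in layout if reg == "FW"})
            seqs[ct] = seq
        sigma = spec.noise_sigma * (spec.noise_floor + frac)
        member_seed = int(rng.integers(2 ** 31))
        fv = make_idealized_fv(spec.cdr_lengths, chains, defs, seqs,
                               name=f"synth-{i:03d}", seed=member_seed,
                               rotamer_choice="random", noise_sigma=sigma,
                               orientation_jitter_deg=spec.orientation_jitter_deg)
        resolution = float(rng.uniform(*spec.resolution_range))
        members.append((fv, resolution))
        truth_members.append({"name": fv.name, "mutation_fraction": float(frac),
                              "noise_sigma": sigma, "resolution": resolution,
                              "seed": member_seed})
    spec_record = asdict(spec)
    spec_record["cdr_lengths"] = {f"{ct}{k}": v for (ct, k), v in
                                  spec.cdr_lengths.items()}
    truth = {"spec": spec_record, "chains": chains, "members": truth_members}
    return members, truth


def make_calibration_table(bin_scales: dict[float, float], n_rows: int,
                           seed: int = 0, kind: str = "synthetic"
                           ) -> tuple["_confidence.CalibrationTable", dict]:
    """Synthetic calibration observations with a known generating distribution.

    ``bin_scales`` maps each conditioning value (identity % or loop length) to
    the scale of an exponential RMSD distribution; rows are assigned uniformly
    across bins.  The generating CDF at conditioning value c is
    ``1 - exp(-x / scale_c)``.  Returns the table and its ground truth.
    """
    if n_rows <= 0:
        raise ValueError("n_rows must be positive")
    if not bin_scales:
        raise ValueError("at least one conditioning bin required")
    rng = np.random.default_rng(seed)
    conds = np.asarray(sorted(bin_scales), dtype=float)
    idx = rng.integers(len(conds), size=n_rows)
    scales = np.array([bin_scales[float(c)] for c in conds])[idx]
    rmsd = rng.exponential(scales)
    table = _confidence.CalibrationTable(conds[idx], rmsd, kind=kind)
    truth = {"bin_scales": {str(k): v for k, v in bin_scales.items()},
             "n_rows": n_rows, "seed": seed}
    return table, truth


def save_family(members, truth: dict, out_dir) -> None:
    """Write a generated family as PDB + FASTA + ground-truth JSON."""
    out = pathlib.Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    index_lines = ["id\tresolution\tchains"]
    for fv, resolution in members:
        write_structure(fv, out / f"{fv.name}.pdb")
        with open(out / f"{fv.name}.fasta", "w") as fh:
            for ct in fv.chains:
                fh.write(f">{fv.name}_{ct}\n{fv.sequence(ct)}\n")
        index_lines.append(f"{fv.name}\t{resolution:.2f}\t{''.join(fv.chains)}")
    (out / "index.tsv").write_text("\n".join(index_lines) + "\n")
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))
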