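"""End-to-end model building and benchmarking.

Order of operations: template selection -> framework assembly (with
orientation transplant for hybrid templates) -> CDR loop modeling in the
fixed order -> partial side-chain prediction -> staged clash resolution ->
per-region confidence annotation and liability scanning.  The modeling path
is deterministic for fixed inputs and configuration; a model is reported as
regions (two frameworks + six CDRs for a paired Fv; one framework + three
CDRs for a single-domain antibody), each with provenance and, where
calibration data allows, the expected RMSD at the configured confidence.
"""

from __future__ import annotations

import json
import time
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import confidence as conf
from .fv_model import (REGION_FW, CdrDefinitionTable, FvSequence, FvStructure,
                       NumberedResidue, assign_regions, pos_key)
from .geometry import _paired_backbone, cdr_rmsd, framework_rmsd, fv_rmsd, \
    kabsch_superpose
from .liabilities import (DEFAULT_EXPOSURE_THRESHOLD, flag_exposure,
                          relative_asa, scan_motifs)
from .loop_graft import (DEFAULT_SCORE_THRESHOLD, DEFAULT_SPAN_TOLERANCE,
                         AbInitioRequired, model_all_cdrs)
from .side_chains import (DEFAULT_CLASH_FACTOR, RotamerLibrary, VdwRadiusTable,
                          partial_side_chain_prediction, resolve_clashes)
from .template_store import (DEFAULT_N_ANCHOR, DEFAULT_RESOLUTION_CUTOFF,
                             TemplateSelection, TemplateStore, _is_identical,
                             build_fragment_stores, pairwise_superimposition_table,
                             select_framework_template)


class PipelineError(RuntimeError):
    pass


@dataclass
class PipelineConfig:
    """Every tunable threshold of the pipeline, serializable to YAML."""

    identity_threshold: float = 80.0      # % FW identity for a global template
    resolution_cutoff: float = 2.5        # Å, template/fragment source filter
    confidence_level: float = 0.75
    exposure_threshold: float = DEFAULT_EXPOSURE_THRESHOLD   # % relative ASA
    n_anchor: int = DEFAULT_N_ANCHOR
    span_tolerance: float = DEFAULT_SPAN_TOLERANCE           # Å
    score_threshold: int = DEFAULT_SCORE_THRESHOLD
    clash_factor: float = DEFAULT_CLASH_FACTOR
    scheme: str = "consensus"
    cdr_definitions: str = "north"
    exclude_identical: bool = True
    side_chains: bool = True
    liabilities: bool = True
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.confidence_level <= 1):
            raise PipelineError("confidence_level must be in (0, 1]")
        if not (0 < self.clash_factor < 1):
            raise PipelineError("clash_factor must be in (0, 1)")
        if self.identity_threshold < 0 or self.identity_threshold > 100:
            raise PipelineError("identity_threshold must be a percentage")
        if self.n_anchor < 2:
            raise PipelineError("n_anchor must be at least 2")

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, source) -> "PipelineConfig":
        if hasattr(source, "read"):
            data = yaml.safe_load(source)
        else:
            try:
                with open(source) as fh:
                    data = yaml.safe_load(fh)
            except (OSError, TypeError):
                data = yaml.safe_load(source)
        return cls(**data)

    def defs(self) -> CdrDefinitionTable:
        return CdrDefinitionTable.load(self.cdr_definitions)


@dataclass
class ModelReport:
    """Provenance, confidence and liabilities for one built model."""

    target: str
    mode: str
    regions: list[dict] = field(default_factory=list)
    clash_stage: str = ""
    liabilities: list[dict] = field(default_factory=list)
    timings: dict = field(default_factory=dict)

    def __post_init__(self):
        names = [r["region"] for r in self.regions]
        if len(names) != len(set(names)):
            raise PipelineError("each modeled region must appear exactly once")

    def region(self, name: str) -> dict:
        for r in self.regions:
            if r["region"] == name:
                return r
        raise KeyError(name)

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=1, default=str)


def assemble_framework(target: FvSequence | FvStructure,
                       selection: TemplateSelection, store: TemplateStore,
                       defs: CdrDefinitionTable) -> FvStructure:
    """Build the initial model from the selected template(s).

    Global mode copies both chains from the single template.  Hybrid mode
    superimposes each donor chain's framework backbone onto the corresponding
    chain of the orientation-source template, so the assembled model inherits
    the source's inter-domain orientation.  Target residue identities
    overwrite template identities on shared framework positions (side chains
    of mutated residues are stripped for later rebuilding); template CDR
    residues are kept as placeholders until loop modeling.
    """
    if isinstance(target, FvStructure):
        target = FvSequence.from_structure(target)
    orientation = store[selection.orientation_id]
    domains: dict[str, list[NumberedResidue]] = {}
    for ct in target.chains:
        donor_id = selection.donor(ct)
        if donor_id is None:
            raise PipelineError(f"selection provides no donor for chain {ct}")
        donor = store[donor_id]
        if not donor.fv.has_chain(ct):
            raise PipelineError(f"donor {donor_id} lacks chain {ct}")
        residues = [r.copy() for r in donor.fv.domain(ct)]
        if selection.mode == "hybrid" and donor_id != orientation.id:
            if not orientation.fv.has_chain(ct):
                raise PipelineError(
                    f"orientation source {orientation.id} lacks chain {ct}")
            mob, ref = _paired_backbone(donor.fv, orientation.fv, ct, REGION_FW)
            if len(mob) < 3:
                raise PipelineError(
                    f"chain {ct}: too few shared FW atoms with orientation source")
            tf, _ = kabsch_superpose(mob, ref)
            for r in residues:
                for a in r.atoms:
                    a.coord = tf.apply(a.coord[None, :])[0]
        tmap = target.chains[ct]
        kept = []
        for r in residues:
            if r.region == REGION_FW:
                if r.position not in tmap:
                    continue
                if tmap[r.position] != r.aa:
                    r.aa = tmap[r.position]
                    r.strip_side_chain()
            kept.append(r)
        missing = set(p for p in tmap
                      if defs.label(ct, p) == REGION_FW) - {r.position for r in kept}
        if missing:
            warnings.warn(f"chain {ct}: {len(missing)} target FW positions absent "
                          "from the template")
        domains[ct] = kept
    fv = FvStructure(heavy=domains.get("H"), light=domains.get("L"),
                     name=f"{target.name or 'target'}_model")
    return assign_regions(fv, defs)


def _expected_rmsd(calibration, kind: str, value: float, level: float):
    if not calibration or kind not in calibration:
        return None
    window = conf.IDENTITY_WINDOW if kind.startswith("fw") else 0.0
    try:
        return conf.expected_rmsd_at_confidence(calibration[kind], value,
                                                p=level, window=window)
    except conf.ConfidenceUnavailable:
        return None


def build_model(target: FvSequence | FvStructure, template_store: TemplateStore,
                fragment_stores: dict, calibration: dict | None = None,
                config: PipelineConfig | None = None
                ) -> tuple[FvStructure, ModelReport]:
    """Run the full pipeline for one target sequence."""
    config = config or PipelineConfig()
    defs = config.defs()
    if isinstance(target, FvStructure):
        target = FvSequence.from_structure(target)
    timings = {}
    t0 = time.perf_counter()
    selection = select_framework_template(
        target, template_store, defs, config.identity_threshold,
        exclude_identical=config.exclude_identical)
    exclude_ids = set()
    if config.exclude_identical:
        exclude_ids = {r.id for r in template_store.records
                       if _is_identical(target, r)}
    timings["template_selection"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model = assemble_framework(target, selection, template_store, defs)
    timings["framework_assembly"] = time.perf_counter() - t0

    t0 = time.perf_counter()
    model, provenance = model_all_cdrs(
        model, target, fragment_stores, defs, n_anchor=config.n_anchor,
        span_tolerance=config.span_tolerance,
        score_threshold=config.score_threshold,
        resolution_cutoff=config.resolution_cutoff, exclude_ids=exclude_ids)
    timings["cdr_modeling"] = time.perf_counter() - t0

    clash_stage = "skipped"
    if config.side_chains:
        t0 = time.perf_counter()
        library = RotamerLibrary.load()
        table = VdwRadiusTable()
        model = partial_side_chain_prediction(model, target, library, table,
                                              config.clash_factor)
        model, clash_stage = resolve_clashes(model, library, table,
                                             config.clash_factor)
        timings["side_chains"] = time.perf_counter() - t0

    regions = []
    for ct in target.chains:
        identity = selection.vh_identity if ct == "H" else selection.vl_identity
        regions.append({
            "region": f"FW-{ct}", "source": selection.donor(ct),
            "stage": selection.mode, "conditioning": identity,
            "expected_rmsd": _expected_rmsd(calibration, f"fw_{ct}", identity,
                                            config.confidence_level)})
    for cdr_name, stage, decoy in provenance:
        ct, k = cdr_name[0], int(cdr_name[1])
        length = len(target.cdr_segment(ct, k, defs))
        regions.append({
            "region": f"CDR{cdr_name}",
            "source": decoy.fragment.source_id if decoy else None,
            "stage": stage, "conditioning": length,
            "anchor_rmsd": round(decoy.anchor_rmsd, 4) if decoy else None,
            "score": decoy.score if decoy else None,
            "expected_rmsd": _expected_rmsd(calibration, cdr_name, length,
                                            config.confidence_level)})

    hits = []
    if config.liabilities and config.side_chains:
        t0 = time.perf_counter()
        rel = relative_asa(model)
        hits = [h.to_dict() for h in
                flag_exposure(scan_motifs(model), rel, config.exposure_threshold)]
        timings["liabilities"] = time.perf_counter() - t0

    report = ModelReport(target=target.name or "target", mode=selection.mode,
                         regions=regions, clash_stage=clash_stage,
                         liabilities=hits, timings=timings)
    return model, report


def build_calibration(structures: list[tuple[FvStructure, float]],
                      template_store: TemplateStore, fragment_stores: dict,
                      config: PipelineConfig | None = None) -> dict:
    """Calibration tables from a structure family.

    Framework tables come from the all-vs-all framework superimpositions
    (VH-VH and VL-VL); CDR tables from leave-one-out loop modeling over the
    family, pairing each loop's length with its achieved backbone RMSD.
    """
    config = config or PipelineConfig()
    defs = config.defs()
    fvs = [s[0] for s in structures]
    tables: dict[str, conf.CalibrationTable] = {}
    for kind, ct in (("vh", "H"), ("vl", "L")):
        if sum(1 for f in fvs if f.has_chain(ct)) >= 2:
            df = pairwise_superimposition_table(fvs, kind)
            tables[f"fw_{ct}"] = conf.CalibrationTable.from_superimpositions(
                df, kind=f"fw_{ct}")
    loop_rows: dict[str, list[tuple[float, float]]] = {}
    loo = PipelineConfig(**{**asdict(config), "exclude_identical": True,
                            "side_chains": False, "liabilities": False})
    for native in fvs:
        target = FvSequence.from_structure(native)
        try:
            model, _report = build_model(target, template_store,
                                         fragment_stores, None, loo)
        except (AbInitioRequired, PipelineError):
            continue
        for ct in native.chains:
            for k in (1, 2, 3):
                length = len(target.cdr_segment(ct, k, defs))
                try:
                    rmsd = cdr_rmsd(model, native, ct, k).rmsd
                except Exception:
                    continue
                loop_rows.setdefault(f"{ct}{k}", []).append((float(length), rmsd))
    for cdr_name, rows in loop_rows.items():
        tables[cdr_name] = conf.CalibrationTable.from_rows(rows, kind=cdr_name)
    return tables


def benchmark(pairs: list[tuple[FvStructure, FvStructure]],
              mode: str = "north") -> pd.DataFrame:
    """Accuracy table for (model, native) pairs.

    Per target: Fv backbone RMSD, per-chain framework RMSD, per-CDR RMSD after
    a single-chain framework fit.  ``mode`` selects the CDR interval set used
    for region assignment ('north' or the 'chothia'-style alternate); only the
    loop boundaries change between modes.
    """
    defs = CdrDefinitionTable.load("chothia" if mode.startswith("chothia")
                                   else "north")
    rows = []
    for model, native in pairs:
        model = assign_regions(model.copy(), defs)
        native = assign_regions(native.copy(), defs)
        row: dict = {"target": native.name}
        try:
            row["fv_rmsd"] = fv_rmsd(model, native).rmsd
        except Exception:
            row["fv_rmsd"] = np.nan
        for ct in native.chains:
            try:
                row[f"fw_{ct}"] = framework_rmsd(model, native, ct).rmsd
            except Exception:
                row[f"fw_{ct}"] = np.nan
            for k in (1, 2, 3):
                try:
                    row[f"cdr_{ct}{k}"] = cdr_rmsd(model, native, ct, k).rmsd
                except Exception:
                    row[f"cdr_{ct}{k}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
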