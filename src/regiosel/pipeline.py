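"""End-to-end analysis pipeline: validate, featurize, train, predict, report.

A run is driven by a single config (YAML/JSON) naming the input bundle —
structure files, the per-site and per-molecule QM descriptor tables, and the
isomer-ratio measurements — plus descriptor and model settings.  Stages:

1. validation: every measured arene has a structure, every enumerated C-H
   site has full descriptor coverage;
2. featurization: symmetry-distinct sites -> canonical competing pairs ->
   fixed-width pair vectors; measurements -> statistical-factor-corrected
   DDG targets;
3. evaluation: LOO (per-pair or grouped per-arene) across the algorithm
   registry, optional greedy feature selection, optional OOS holdout;
4. prediction: pairwise DDGs from the full-data fit, reduced to per-site
   scores and Boltzmann site probabilities per arene.

Every artifact records the config hash and seed; re-running the same config
reproduces the same artifacts.  Logging goes to stderr, machine-readable
output to files only.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import joblib
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .geometry import read_structure
from .harness import (
    PairDataset,
    build_model,
    compare_algorithms,
    greedy_feature_selection,
    loo_evaluate,
    oos_evaluate,
    registry_names,
)
from .selectivity import (
    SelectivityMeasurement,
    aggregate_site_scores,
    measurement_to_pair_targets,
    parse_ratio,
    site_probabilities,
)
from .sites import (
    DEFAULT_SCHEMA,
    DescriptorSchema,
    SiteDescriptors,
    build_pair_vector,
    canonical_pair_order,
    enumerate_sites,
    load_molecule_table,
    load_qm_table,
    site_steric_block,
)

__all__ = [
    "RunConfig",
    "ValidationReport",
    "featurize_bundle",
    "load_measurements",
    "load_model",
    "run_pipeline",
    "save_model",
    "validate_inputs",
]

logger = logging.getLogger("regiosel")

_STRUCTURE_EXTS = (".xyz", ".sdf", ".mol")


@dataclass(frozen=True)
class RunConfig:
    """Validated run configuration; unknown keys are rejected on load."""

    structures_dir: str
    qm_sites: str
    qm_molecules: str
    measurements: str
    out_dir: str = "regiosel_run"
    algorithm: str = "extra_trees"
    algorithms: tuple[str, ...] | None = None   # None -> full registry
    seed: int = 0
    mode: str = "pair"                          # LOO unit: "pair" | "arene"
    holdout: tuple[str, ...] = ()               # arene ids for OOS
    select_features: bool = False
    selection_tolerance: float = 1e-3
    default_temperature: float = 333.15         # K, when measurements omit it
    sterimol_site_mode: str = "flanking"
    sterimol_shell: int = 3
    bv_sphere_radius: float = 3.5      # A
    bv_grid_spacing: float = 0.05      # A
    atom_index_base: int = 0

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        raw = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") \
            else json.loads(text)
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        missing = [k for k in ("structures_dir", "qm_sites", "qm_molecules",
                               "measurements") if k not in raw]
        if missing:
            raise ValueError(f"config missing required keys: {missing}")
        raw = dict(raw)
        for key in ("algorithms", "holdout"):
            if raw.get(key) is not None:
                raw[key] = tuple(raw[key])
        cfg = cls(**raw)
        if cfg.mode not in ("pair", "arene"):
            raise ValueError(f"mode must be 'pair' or 'arene', got {cfg.mode!r}")
        if cfg.algorithm not in registry_names():
            raise ValueError(f"unknown algorithm {cfg.algorithm!r}")
        return cfg

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True, default=list)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# measurements
# ---------------------------------------------------------------------------

def load_measurements(path: str | Path,
                      default_temperature: float = 333.15,
                      ) -> list[SelectivityMeasurement]:
    """Read the measurements CSV.

    Columns: ``arene_id, class_label, fraction`` (or a ``ratio`` column with
    strings like ``"17:1"`` spanning the arene's classes in row order),
    ``multiplicity`` and optional ``temperature_K``.  Fractions are
    renormalized over the measured classes.
    """
    df = pd.read_csv(path)
    for col in ("arene_id", "class_label", "multiplicity"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    if "fraction" not in df.columns and "ratio" not in df.columns:
        raise ValueError(f"{path}: need a 'fraction' or 'ratio' column")
    out = []
    for arene_id, grp in df.groupby("arene_id", sort=True):
        labels = [str(l) for l in grp["class_label"]]
        if len(set(labels)) != len(labels):
            raise ValueError(f"{path}: duplicate class label for arene {arene_id}")
        if "fraction" in grp.columns and grp["fraction"].notna().all():
            fracs = [float(f) for f in grp["fraction"]]
        else:
            ratio = str(grp["ratio"].iloc[0])
            fracs = parse_ratio(ratio)
            if len(fracs) != len(labels):
                raise ValueError(
                    f"{path}: ratio {ratio!r} has {len(fracs)} parts for "
                    f"{len(labels)} classes of arene {arene_id}")
        total = sum(fracs)
        fracs = [f / total for f in fracs]
        if "temperature_K" in grp.columns and grp["temperature_K"].notna().all():
            temp = float(grp["temperature_K"].iloc[0])
        else:
            temp = default_temperature
        out.append(SelectivityMeasurement(
            arene_id=str(arene_id),
            fractions=dict(zip(labels, fracs)),
            multiplicities={l: int(m) for l, m in zip(labels, grp["multiplicity"])},
            temperature=temp,
        ))
    return out


# ---------------------------------------------------------------------------
# validation
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    violations: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations


def _structure_files(structures_dir: str | Path) -> dict[str, Path]:
    d = Path(structures_dir)
    if not d.is_dir():
        raise IOError(f"structures directory not found: {d}")
    return {p.stem: p for p in sorted(d.iterdir())
            if p.suffix.lower() in _STRUCTURE_EXTS}


def validate_inputs(structures_dir: str | Path,
                    qm_sites_path: str | Path,
                    qm_molecules_path: str | Path,
                    measurements_path: str | Path,
                    default_temperature: float = 333.15,
                    index_base: int = 0) -> ValidationReport:
    """Cross-check the input bundle; returns all violations found."""
    report = ValidationReport()
    files = _structure_files(structures_dir)
    for p in (qm_sites_path, qm_molecules_path, measurements_path):
        if not Path(p).is_file():
            raise IOError(f"input file not found: {p}")
    qm_sites = load_qm_table(qm_sites_path, index_base=index_base)
    qm_mols = load_molecule_table(qm_molecules_path)
    measurements = load_measurements(measurements_path, default_temperature)

    for m in measurements:
        if m.arene_id not in files:
            report.violations.append(
                f"measurement references unknown arene {m.arene_id!r}")
            continue
        mol = read_structure(files[m.arene_id])
        classes = {c.label: c for c in enumerate_sites(mol)}
        if m.arene_id not in qm_mols:
            report.violations.append(
                f"arene {m.arene_id!r} missing from molecule descriptor table")
        for label in m.fractions:
            if label not in classes:
                report.violations.append(
                    f"arene {m.arene_id!r}: measured class {label!r} not among "
                    f"enumerated site classes {sorted(classes)}")
                continue
            if classes[label].multiplicity != m.multiplicities[label]:
                report.violations.append(
                    f"arene {m.arene_id!r} class {label!r}: multiplicity "
                    f"{m.multiplicities[label]} does not match enumerated "
                    f"{classes[label].multiplicity}")
            for atom in classes[label].atom_indices:
                if (m.arene_id, atom) not in qm_sites:
                    report.violations.append(
                        f"QM table missing site (arene {m.arene_id!r}, "
                        f"atom {atom})")
    return report


# ---------------------------------------------------------------------------
# featurization
# ---------------------------------------------------------------------------

def featurize_bundle(structures_dir: str | Path,
                     qm_sites_path: str | Path,
                     qm_molecules_path: str | Path,
                     measurements: Sequence[SelectivityMeasurement],
                     schema: DescriptorSchema = DEFAULT_SCHEMA,
                     sterimol_site_mode: str = "flanking",
                     sterimol_shell: int = 3,
                     sphere_radius: float = 3.5,
                     grid_spacing: float = 0.05,
                     index_base: int = 0) -> PairDataset:
    """Competing-pair dataset from structures + QM tables + measurements.

    For every measured arene, sites are enumerated, the steric block is
    computed at each class representative, the electronic block is joined
    from the QM table, and every canonical pair of measured classes becomes
    one row with the statistical-factor-corrected DDG target.
    """
    files = _structure_files(structures_dir)
    qm_sites = load_qm_table(qm_sites_path, index_base=index_base)
    qm_mols = load_molecule_table(qm_molecules_path)

    vectors, targets = [], []
    for m in measurements:
        if m.arene_id not in files:
            raise KeyError(f"no structure for measured arene {m.arene_id!r}")
        mol = read_structure(files[m.arene_id])
        classes = {c.label: c for c in enumerate_sites(mol)}
        mol_desc = qm_mols[m.arene_id]
        site_desc: dict[str, SiteDescriptors] = {}
        for label in sorted(m.fractions):
            cls = classes[label]
            rep = cls.representative
            steric = site_steric_block(
                mol, rep, mode=sterimol_site_mode, shell=sterimol_shell,
                sphere_radius=sphere_radius, grid_spacing=grid_spacing)
            elec = qm_sites[(m.arene_id, rep)]
            site_desc[label] = SiteDescriptors(
                arene_id=m.arene_id, atom_index=rep,
                values={**elec.values, **steric}, class_label=label)
        for t in measurement_to_pair_targets(m):
            first, second, sign = canonical_pair_order(
                classes[t.class_a], classes[t.class_b])
            a_lab = [l for l, c in classes.items() if c is first][0]
            b_lab = [l for l, c in classes.items() if c is second][0]
            vectors.append(build_pair_vector(
                site_desc[a_lab], site_desc[b_lab], mol_desc,
                m.temperature, schema))
            targets.append(dataclasses.replace(
                t, class_a=a_lab, class_b=b_lab,
                ddg_app=sign * t.ddg_app))
    return PairDataset.from_pairs(vectors, targets,
                                  metadata={"source": str(structures_dir)})


# ---------------------------------------------------------------------------
# model persistence
# ---------------------------------------------------------------------------

def save_model(model, feature_names: Sequence[str], path: str | Path,
               seed: int = 0) -> str:
    """Persist a fitted model with its feature-schema hash; returns the hash."""
    schema_hash = hashlib.sha256(
        json.dumps(list(feature_names)).encode()).hexdigest()[:16]
    joblib.dump({"model": model, "feature_names": list(feature_names),
                 "schema_hash": schema_hash, "seed": seed,
                 "version": __version__}, path)
    return schema_hash


def load_model(path: str | Path, feature_names: Sequence[str]):
    """Load a persisted model; refuses a feature-schema mismatch."""
    blob = joblib.load(path)
    expected = hashlib.sha256(
        json.dumps(list(feature_names)).encode()).hexdigest()[:16]
    if blob["schema_hash"] != expected:
        raise ValueError(
            "model schema hash mismatch: archive was trained on "
            f"{blob['feature_names']}, requested {list(feature_names)}")
    return blob["model"]


# ---------------------------------------------------------------------------
# full pipeline
# ---------------------------------------------------------------------------

def predict_site_outcomes(data: PairDataset, model,
                          measurements: Sequence[SelectivityMeasurement],
                          ) -> dict[str, dict]:
    """Per-arene site scores and Boltzmann probabilities from pair DDGs."""
    pred = model.predict(data.X)
    by_arene: dict[str, list[tuple[str, str, float]]] = {}
    for (arene, ca, cb), p in zip(data.pair_ids, pred):
        by_arene.setdefault(arene, []).append((ca, cb, float(p)))
    mults = {m.arene_id: m.multiplicities for m in measurements}
    temps = {m.arene_id: m.temperature for m in measurements}
    out: dict[str, dict] = {}
    for arene, pairs in sorted(by_arene.items()):
        if len({s for p in pairs for s in p[:2]}) < 2:
            continue
        scores = aggregate_site_scores(pairs)
        sp = site_probabilities(scores, mults[arene], temps[arene], arene)
        out[arene] = {
            "scores": {k: round(v, 6) for k, v in scores.items()},
            "probabilities": {k: round(v, 6)
                              for k, v in sp.probabilities.items()},
            "temperature_K": temps[arene],
        }
    return out


def run_pipeline(config: RunConfig) -> Path:
    """Validate -> featurize -> evaluate -> predict -> report.

    Writes ``pairs.csv``, ``report.json`` and ``predictions.json`` under
    ``config.out_dir`` and returns that directory.  Raises on validation
    violations.
    """
    chash = config.config_hash()
    logger.info("regiosel %s | config %s | seed %d", __version__, chash,
                config.seed)
    report = validate_inputs(
        config.structures_dir, config.qm_sites, config.qm_molecules,
        config.measurements, config.default_temperature,
        config.atom_index_base)
    if not report.ok:
        raise ValueError("input validation failed:\n  "
                         + "\n  ".join(report.violations))
    measurements = load_measurements(config.measurements,
                                     config.default_temperature)
    data = featurize_bundle(
        config.structures_dir, config.qm_sites, config.qm_molecules,
        measurements, sterimol_site_mode=config.sterimol_site_mode,
        sterimol_shell=config.sterimol_shell,
        sphere_radius=config.bv_sphere_radius,
        grid_spacing=config.bv_grid_spacing,
        index_base=config.atom_index_base)
    logger.info("featurized %d pairs x %d features from %d arenes",
                data.n_rows, data.X.shape[1], len(set(data.arene_ids)))

    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(data.X, columns=data.feature_names).assign(
        arene_id=data.arene_ids,
        class_a=[p[1] for p in data.pair_ids],
        class_b=[p[2] for p in data.pair_ids],
        ddg_app_kcal_mol=data.y,
    ).to_csv(out_dir / "pairs.csv", index=False)

    reports = compare_algorithms(
        data, config.algorithms, seed=config.seed, mode=config.mode)
    result: dict = {
        "version": __version__,
        "config_hash": chash,
        "seed": config.seed,
        "mode": config.mode,
        "n_pairs": data.n_rows,
        "n_arenes": len(set(data.arene_ids)),
        "algorithms": [
            {k: v for k, v in r.to_dict().items()
             if k not in ("predictions", "actual")}
            for r in reports],
        "best_algorithm": reports[0].algorithm,
    }
    if config.select_features:
        subset, _ = greedy_feature_selection(
            data, config.algorithm, seed=config.seed, mode=config.mode,
            tolerance=config.selection_tolerance)
        result["selected_features"] = list(subset)
        result["selected_loo"] = {
            k: v for k, v in loo_evaluate(
                data.select_features(subset), config.algorithm,
                seed=config.seed, mode=config.mode).to_dict().items()
            if k not in ("predictions", "actual")}
    if config.holdout:
        oos = oos_evaluate(data, config.holdout, config.algorithm,
                           seed=config.seed)
        result["oos"] = {k: v for k, v in oos.to_dict().items()
                        if k not in ("predictions", "actual")}
    (out_dir / "report.json").write_text(json.dumps(result, indent=2,
                                                    sort_keys=True))

    model = build_model(config.algorithm, config.seed)
    model.fit(data.X, data.y)
    save_model(model, data.feature_names, out_dir / "model.joblib",
               seed=config.seed)
    predictions = predict_site_outcomes(data, model, measurements)
    (out_dir / "predictions.json").write_text(
        json.dumps({"config_hash": chash, "seed": config.seed,
                    "arenes": predictions}, indent=2, sort_keys=True))
    logger.info("artifacts written to %s", out_dir)
    return out_dir
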