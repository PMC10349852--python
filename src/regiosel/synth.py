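"""Synthetic fixtures and datasets with a known ground-truth mechanism.

Two layers:

* **Geometry fixtures** — ideal-geometry arenes (planar ring, C-C 1.39 A,
  C-H 1.09 A) built from a substituent vocabulary over a benzene ring plus
  named heteroarene/fused templates (thiophene, furan, naphthalene).  These
  exercise bond perception, site enumeration and the steric descriptors
  with exactly known answers.
* **Descriptor datasets** — competing-site pair datasets whose per-site
  descriptors are drawn from loosely physical distributions and whose true
  pairwise target is a linear function of the descriptor difference,

      DDG(A, B) = w . (d_A - d_B)
                  + c_redox * E_ox * (f-_A - f-_B) + N(0, sigma),

  exactly antisymmetric by construction.  The generating weights are
  returned so recovery can be asserted.  The default mechanism is dominated
  by the Fukui f- of the reacting site (electrophilic/radical-cation
  attack), with secondary steric (%Vbur, B5) and C-H BDE contributions.  A
  "tree-friendly" variant adds threshold interactions that a linear model
  cannot represent.

All randomness flows from a single integer seed; the same seed reproduces
the dataset bit for bit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .geometry import Molecule3D, write_xyz
from .selectivity import (
    SelectivityMeasurement,
    site_probabilities,
)
from .sites import (
    DEFAULT_SCHEMA,
    DescriptorSchema,
    MoleculeDescriptors,
    SiteDescriptors,
    build_pair_vector,
)
from .harness import PairDataset

__all__ = [
    "GeneratorConfig",
    "SUBSTITUENT_VOCABULARY",
    "RING_TEMPLATES",
    "generate_synthetic_dataset",
    "make_ring_fixture",
    "simulate_measurements",
    "write_bundle",
]

# ---------------------------------------------------------------------------
# ideal-geometry ring fixtures
# ---------------------------------------------------------------------------

_CC_AROMATIC = 1.39
_CH = 1.09
_CC_SINGLE = 1.50
_CO = 1.36
_O_CME = 1.43
_CF = 1.35
_CCL = 1.74
_CBR = 1.90
_C_CN = 1.43
_CN_TRIPLE = 1.16
_COS_TET = -1.0 / 3.0              # cos(109.47 deg)
_SIN_TET = math.sqrt(1 - _COS_TET**2)

SUBSTITUENT_VOCABULARY = ("H", "Me", "Et", "OMe", "F", "Cl", "Br", "CN")
RING_TEMPLATES = ("benzene", "naphthalene", "thiophene", "furan")


def _sp3_cap(pos: np.ndarray, toward_parent: np.ndarray, perp1: np.ndarray,
             perp2: np.ndarray, n_h: int, phase: float = 0.0):
    """Tetrahedral C-H vectors around an sp3 carbon at *pos*.

    ``toward_parent`` is the unit vector from the carbon to the atom it is
    bonded to; hydrogens are placed at 109.47 deg from that bond, fanned at
    equal azimuths starting at *phase* (radians).
    """
    out = []
    for k in range(n_h):
        phi = phase + 2 * math.pi * k / 3
        d = _COS_TET * toward_parent + _SIN_TET * (
            math.cos(phi) * perp1 + math.sin(phi) * perp2)
        out.append(pos + _CH * d)
    return out


def _attach(elements: list[str], coords: list[np.ndarray], token: str,
            ipso: np.ndarray, radial: np.ndarray, tangent: np.ndarray,
            normal: np.ndarray) -> None:
    """Append substituent *token* atoms bonded to the ring atom at *ipso*.

    ``radial`` points outward from the ring center through ipso; ``tangent``
    and ``normal`` complete a right-handed in-plane/out-of-plane frame.
    """
    if token == "H":
        elements.append("H")
        coords.append(ipso + _CH * radial)
    elif token in ("F", "Cl", "Br"):
        length = {"F": _CF, "Cl": _CCL, "Br": _CBR}[token]
        elements.append(token)
        coords.append(ipso + length * radial)
    elif token == "CN":
        c = ipso + _C_CN * radial
        elements += ["C", "N"]
        coords += [c, c + _CN_TRIPLE * radial]
    elif token == "Me":
        c = ipso + _CC_SINGLE * radial
        elements.append("C")
        coords.append(c)
        for h in _sp3_cap(c, -radial, tangent, normal, 3, phase=math.pi / 2):
            elements.append("H")
            coords.append(h)
    elif token == "Et":
        c1 = ipso + _CC_SINGLE * radial
        # C-C-C ~ 111 deg, beta carbon out of the ring plane
        d2 = _COS_TET * (-radial) + _SIN_TET * normal
        c2 = c1 + 1.53 * np.asarray(d2)
        elements += ["C", "C"]
        coords += [c1, c2]
        # two methylene H's
        perp = np.cross(d2, -radial)
        perp /= np.linalg.norm(perp)
        bis = -(-radial + np.asarray(d2))
        bis /= np.linalg.norm(bis)
        for s in (+1, -1):
            d = _SIN_TET * 0.94 * s * perp + 0.6 * bis
            d /= np.linalg.norm(d)
            elements.append("H")
            coords.append(c1 + _CH * d)
        # methyl cap on c2
        axis_back = (c1 - c2) / np.linalg.norm(c1 - c2)
        p1 = perp
        p2 = np.cross(axis_back, p1)
        for h in _sp3_cap(c2, axis_back, p1, p2, 3):
            elements.append("H")
            coords.append(h)
    elif token == "OMe":
        o = ipso + _CO * radial
        # C(ipso)-O-C(methyl) ~ 117 deg, methyl in the ring plane
        ang = math.radians(117.0)
        d = math.cos(ang) * (-radial) + math.sin(ang) * tangent
        c = o + _O_CME * np.asarray(d)
        elements += ["O", "C"]
        coords += [o, c]
        axis_back = (o - c) / np.linalg.norm(o - c)
        p1 = normal
        p2 = np.cross(axis_back, p1)
        for h in _sp3_cap(c, axis_back, p1, p2, 3):
            elements.append("H")
            coords.append(h)
    else:
        raise ValueError(
            f"unknown substituent token {token!r}; vocabulary: "
            f"{SUBSTITUENT_VOCABULARY}"
        )


def _benzene_frame(pattern: Mapping[int, str], identifier: str) -> Molecule3D:
    """Six-ring with substituents at 1-based positions per *pattern*."""
    elements: list[str] = []
    coords: list[np.ndarray] = []
    normal = np.array([0.0, 0.0, 1.0])
    ring_pos = []
    for k in range(6):
        theta = math.radians(60.0 * k)
        ring_pos.append(_CC_AROMATIC * np.array(
            [math.cos(theta), math.sin(theta), 0.0]))
        elements.append("C")
        coords.append(ring_pos[-1])
    for k in range(6):
        token = pattern.get(k + 1, "H")
        radial = ring_pos[k] / np.linalg.norm(ring_pos[k])
        tangent = np.cross(normal, radial)
        _attach(elements, coords, token, ring_pos[k], radial, tangent, normal)
    return Molecule3D(elements=elements, coordinates=np.array(coords),
                      identifier=identifier)


def _naphthalene() -> Molecule3D:
    a = _CC_AROMATIC
    dx = a * math.cos(math.radians(30))
    dy = a * math.sin(math.radians(30))
    # bridgeheads on the y-axis, two fused ideal hexagons
    carbons = [
        (0.0, dy), (0.0, -dy),
        (dx, a), (2 * dx, dy), (2 * dx, -dy), (dx, -a),
        (-dx, a), (-2 * dx, dy), (-2 * dx, -dy), (-dx, -a),
    ]
    elements = ["C"] * len(carbons)
    coords = [np.array([x, y, 0.0]) for x, y in carbons]
    pos = {i: c for i, c in enumerate(coords)}
    # hydrogens on the eight CH carbons, along the exterior bisector
    for i in range(2, 10):
        nbrs = [j for j, c in pos.items()
                if j != i and np.linalg.norm(c - pos[i]) < 1.45]
        d = -sum((pos[j] - pos[i]) / np.linalg.norm(pos[j] - pos[i])
                 for j in nbrs)
        d = d / np.linalg.norm(d)
        elements.append("H")
        coords.append(pos[i] + _CH * d)
    return Molecule3D(elements=elements, coordinates=np.array(coords),
                      identifier="naphthalene")


def _five_ring(heteroatom: str) -> Molecule3D:
    """Thiophene/furan-type planar five-ring with idealized bond lengths."""
    sx = {"S": 1.714, "O": 1.362}[heteroatom]   # X-C2 bond length
    half_angle = {"S": math.radians(46.0), "O": math.radians(53.3)}[heteroatom]
    c34_half = {"S": 0.7115, "O": 0.7155}[heteroatom]
    x_y = {"S": 1.189, "O": 1.163}[heteroatom]
    x2 = sx * math.sin(half_angle)
    y2 = x_y - sx * math.cos(half_angle)
    c23 = 1.37
    dxx = x2 - c34_half
    y3 = y2 - math.sqrt(max(c23**2 - dxx**2, 0.25))
    elements = [heteroatom, "C", "C", "C", "C"]
    coords = [
        np.array([0.0, x_y, 0.0]),
        np.array([x2, y2, 0.0]), np.array([c34_half, y3, 0.0]),
        np.array([-c34_half, y3, 0.0]), np.array([-x2, y2, 0.0]),
    ]
    pos = list(coords)
    for i in range(1, 5):
        nbrs = [j for j in range(5)
                if j != i and np.linalg.norm(pos[j] - pos[i]) < 1.80]
        d = -sum((pos[j] - pos[i]) / np.linalg.norm(pos[j] - pos[i])
                 for j in nbrs)
        d = d / np.linalg.norm(d)
        elements.append("H")
        coords.append(pos[i] + _CH * d)
    return Molecule3D(elements=elements, coordinates=np.array(coords),
                      identifier="thiophene" if heteroatom == "S" else "furan")


def make_ring_fixture(
    pattern: Mapping[int, str] | str | None = None,
    identifier: str | None = None,
) -> Molecule3D:
    """Deterministic ideal-geometry arene fixture.

    *pattern* is either a mapping {1-based ring position -> substituent
    token} over a benzene ring (empty/None -> benzene itself) or one of the
    named templates ``benzene``, ``naphthalene``, ``thiophene``, ``furan``.
    """
    if isinstance(pattern, str):
        if pattern == "benzene":
            mol = _benzene_frame({}, "benzene")
        elif pattern == "naphthalene":
            mol = _naphthalene()
        elif pattern == "thiophene":
            mol = _five_ring("S")
        elif pattern == "furan":
            mol = _five_ring("O")
        else:
            raise ValueError(
                f"unknown template {pattern!r}; templates: {RING_TEMPLATES}")
    else:
        pattern = dict(pattern or {})
        bad = [p for p in pattern if not 1 <= int(p) <= 6]
        if bad:
            raise ValueError(f"ring positions must be 1..6, got {bad}")
        name = identifier or (
            "benzene" if not pattern else
            "_".join(f"{tok}{p}" for p, tok in sorted(pattern.items())))
        mol = _benzene_frame({int(p): t for p, t in pattern.items()}, name)
    if identifier is not None:
        mol.identifier = identifier
    return mol


# ---------------------------------------------------------------------------
# synthetic descriptor datasets
# ---------------------------------------------------------------------------

# Loosely physical per-site distributions (mean, sd); not fitted to any data.
DEFAULT_DISTRIBUTIONS: dict[str, tuple[float, float]] = {
    "percent_buried_volume": (35.0, 8.0),    # %, truncated to [0, 100]
    "sterimol_L": (3.5, 0.8),                # A
    "sterimol_B1": (1.7, 0.3),               # A
    "sterimol_B5": (3.2, 0.7),               # A, floored at B1
    "fukui_plus": (0.05, 0.02),              # e
    "fukui_minus": (0.05, 0.02),             # e
    "fukui_zero": (0.05, 0.02),              # e
    "partial_charge": (-0.05, 0.05),         # e
    "ch_bde": (112.0, 3.0),                  # kcal/mol
    "ext_1": (0.0, 1.0),
    "ext_2": (0.0, 1.0),
    "ext_3": (0.0, 1.0),
}
DEFAULT_REDOX_DISTRIBUTION = (1.9, 0.25)      # V vs SCE, computed E_ox

# Ground-truth weights (kcal/mol per descriptor unit) on the per-site block.
# Fukui f- of the reacting site dominates; sterics and C-H BDE are secondary.
DEFAULT_WEIGHTS: dict[str, float] = {
    "fukui_minus": 30.0,
    "percent_buried_volume": -0.04,
    "ch_bde": -0.08,
    "sterimol_B5": -0.30,
}
DEFAULT_REDOX_COUPLING = 5.0  # kcal/mol per (V * e): E_ox modulates the f- slope


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for the synthetic competing-site generator."""

    n_pairs: int = 150
    min_classes: int = 2
    max_classes: int = 4
    distributions: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DISTRIBUTIONS))
    redox_distribution: tuple[float, float] = DEFAULT_REDOX_DISTRIBUTION
    weights: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_WEIGHTS))
    redox_coupling: float = DEFAULT_REDOX_COUPLING
    noise_sigma: float = 0.25          # kcal/mol
    temperature: float = 333.15        # K
    mechanism: str = "linear"          # or "tree_friendly"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sigma < 0:
            raise ValueError("noise sigma must be >= 0")
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if not 2 <= self.min_classes <= self.max_classes:
            raise ValueError("need 2 <= min_classes <= max_classes")
        if any(not np.isfinite(w) for w in self.weights.values()):
            raise ValueError("non-finite ground-truth weights")
        unknown = set(self.weights) - set(self.distributions)
        if unknown:
            raise ValueError(f"weights on undeclared descriptors: {sorted(unknown)}")
        if self.mechanism not in ("linear", "tree_friendly"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")


def _sample_site(rng: np.random.Generator,
                 dists: Mapping[str, tuple[float, float]]) -> dict[str, float]:
    v: dict[str, float] = {}
    for name, (mu, sd) in dists.items():
        v[name] = float(rng.normal(mu, sd))
    v["percent_buried_volume"] = float(np.clip(v["percent_buried_volume"], 0.0, 100.0))
    v["sterimol_L"] = max(v["sterimol_L"], 0.5)
    v["sterimol_B1"] = max(v["sterimol_B1"], 0.5)
    v["sterimol_B5"] = max(v["sterimol_B5"], v["sterimol_B1"])
    v["fukui_plus"] = abs(v["fukui_plus"])
    v["fukui_minus"] = abs(v["fukui_minus"])
    v["fukui_zero"] = abs(v["fukui_zero"])
    v["dual_descriptor"] = v["fukui_plus"] - v["fukui_minus"]
    return v


def _site_score(values: Mapping[str, float], redox: float,
                cfg: GeneratorConfig) -> float:
    if cfg.mechanism == "tree_friendly":
        # piecewise-constant ground truth: axis-aligned reactivity steps
        # (with one interaction) that tree ensembles represent natively and
        # a linear model cannot
        g = 0.0
        if values["fukui_minus"] > 0.05:
            g += 1.5
        if values["fukui_minus"] > 0.07:
            g += 0.8
        if values["percent_buried_volume"] > 38.0:
            g -= 1.2
        if values["ch_bde"] < 111.0 and values["fukui_minus"] > 0.045:
            g += 1.0
        if redox > 1.9 and values["partial_charge"] < -0.05:
            g += 0.7
        return g
    g = sum(w * values[name] for name, w in cfg.weights.items())
    g += cfg.redox_coupling * redox * values["fukui_minus"]
    return float(g)


_CLASS_LABELS = "abcdefghijklmnopqrstuvwxyz"


def generate_synthetic_dataset(
    config: GeneratorConfig,
    schema: DescriptorSchema = DEFAULT_SCHEMA,
    augment: bool = False,
) -> tuple[PairDataset, dict]:
    """Pair dataset with known generating mechanism.

    Arenes are drawn until ``config.n_pairs`` competing pairs exist (the
    last arene's pair list may be truncated).  Each arene gets 2-4 site
    classes with multiplicities in {1, 2}; class descriptors come from
    ``config.distributions`` and the true pairwise target is
    ``score(A) - score(B) + noise``, oriented a-before-b (the canonical pair
    order).  With ``augment=True`` each pair also appears swapped with the
    exactly negated target, making the training relation antisymmetric.

    Returns the dataset and a ground-truth record (weights, per-class
    scores and descriptor values, multiplicities) for recovery tests.
    """
    from .selectivity import PairTarget

    rng = np.random.default_rng(config.seed)
    vectors = []
    targets: list[PairTarget] = []
    n_unordered = 0
    truth_scores: dict[str, dict[str, float]] = {}
    truth_mults: dict[str, dict[str, int]] = {}
    truth_sites: dict[str, dict[str, dict[str, float]]] = {}
    truth_redox: dict[str, float] = {}
    arene_counter = 0
    while n_unordered < config.n_pairs:
        arene_id = f"arene_{arene_counter:03d}"
        arene_counter += 1
        k = int(rng.integers(config.min_classes, config.max_classes + 1))
        redox = float(rng.normal(*config.redox_distribution))
        mol_desc = MoleculeDescriptors(arene_id=arene_id,
                                       values={"redox_potential": redox})
        labels = [_CLASS_LABELS[i] for i in range(k)]
        sites: dict[str, SiteDescriptors] = {}
        scores: dict[str, float] = {}
        mults: dict[str, int] = {}
        for j, lab in enumerate(labels):
            values = _sample_site(rng, config.distributions)
            sites[lab] = SiteDescriptors(arene_id=arene_id, atom_index=j,
                                         values=values, class_label=lab)
            scores[lab] = _site_score(values, redox, config)
            mults[lab] = int(rng.integers(1, 3))
        truth_scores[arene_id] = scores
        truth_mults[arene_id] = mults
        truth_sites[arene_id] = {lab: dict(s.values) for lab, s in sites.items()}
        truth_redox[arene_id] = redox
        for i, la in enumerate(labels):
            for lb in labels[i + 1:]:
                if n_unordered >= config.n_pairs:
                    break
                eps = float(rng.normal(0.0, config.noise_sigma)) \
                    if config.noise_sigma > 0 else 0.0
                ddg = scores[la] - scores[lb] + eps
                vectors.append(build_pair_vector(
                    sites[la], sites[lb], mol_desc, config.temperature, schema))
                targets.append(PairTarget(arene_id, la, lb, ddg))
                n_unordered += 1
                if augment:
                    vectors.append(build_pair_vector(
                        sites[lb], sites[la], mol_desc, config.temperature,
                        schema))
                    targets.append(PairTarget(arene_id, lb, la, -ddg))
    data = PairDataset.from_pairs(
        vectors, targets,
        metadata={"generator": "synthetic", "seed": config.seed,
                  "noise_sigma": config.noise_sigma,
                  "mechanism": config.mechanism, "augmented": augment},
    )
    truth = {
        "weights": dict(config.weights),
        "redox_coupling": config.redox_coupling,
        "scores": truth_scores,
        "multiplicities": truth_mults,
        "site_values": truth_sites,
        "redox": truth_redox,
        "noise_sigma": config.noise_sigma,
        "temperature": config.temperature,
        "mechanism": config.mechanism,
    }
    return data, truth


def simulate_measurements(
    truth: Mapping,
    temperature: float | None = None,
    counting_noise: int | None = None,
    seed: int = 0,
) -> list[SelectivityMeasurement]:
    """Isomer distributions implied by the generated true site scores.

    Fractions follow the multiplicity-weighted Boltzmann distribution at
    *temperature* (default: the generator's).  ``counting_noise=N`` replaces
    each distribution by multinomial frequencies from N product counts,
    emulating an integration/detection limit; zero-count classes get a
    half-count floor so ratios stay finite.
    """
    T = float(temperature if temperature is not None else truth["temperature"])
    rng = np.random.default_rng(seed)
    out: list[SelectivityMeasurement] = []
    for arene_id in sorted(truth["scores"]):
        scores = truth["scores"][arene_id]
        mults = truth["multiplicities"][arene_id]
        sp = site_probabilities(scores, mults, T, arene_id=arene_id)
        fracs = dict(sp.probabilities)
        if counting_noise:
            labels = sorted(fracs)
            counts = rng.multinomial(counting_noise, [fracs[l] for l in labels])
            counts = np.maximum(counts.astype(float), 0.5)
            total = counts.sum()
            fracs = {l: float(c / total) for l, c in zip(labels, counts)}
        out.append(SelectivityMeasurement(
            arene_id=arene_id, fractions=fracs,
            multiplicities=dict(mults), temperature=T))
    return out


# ---------------------------------------------------------------------------
# on-disk bundles in the real pipeline formats
# ---------------------------------------------------------------------------

def write_bundle(config: GeneratorConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write a self-consistent synthetic input bundle.

    Produces, in exactly the formats the analysis pipeline reads:
    ``structures/*.xyz`` (ideal-geometry arenes from the substituent
    vocabulary), ``qm_sites.csv`` (per-site electronic descriptors, one row
    per aromatic C-H atom), ``qm_molecules.csv`` (redox potentials) and
    ``measurements.csv`` (isomer fractions per symmetry class).  Selectivity
    is driven by the electronic part of the generating mechanism evaluated
    on the sampled QM values, so the bundle has a learnable signal.
    """
    from .sites import enumerate_sites  # local import to avoid cycle at init

    out_dir = Path(out_dir)
    (out_dir / "structures").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(config.seed)

    patterns: list[tuple[str, Mapping[int, str] | str]] = [
        ("benzene", "benzene"),
        ("thiophene", "thiophene"),
        ("furan", "furan"),
        ("naphthalene", "naphthalene"),
        ("anisole", {1: "OMe"}),
        ("toluene", {1: "Me"}),
        ("o_xylene", {1: "Me", 2: "Me"}),
        ("fluorobenzene", {1: "F"}),
        ("chloroanisole", {1: "OMe", 4: "Cl"}),
        ("benzonitrile", {1: "CN"}),
        ("ethylbenzene", {1: "Et"}),
        ("p_cresol_me", {1: "OMe", 4: "Me"}),
    ]

    site_rows = []
    mol_rows = []
    meas_rows = []
    elec_weights = {k: w for k, w in config.weights.items()
                    if k in ("fukui_minus", "fukui_plus", "fukui_zero",
                             "partial_charge", "ch_bde", "dual_descriptor")}
    for name, pattern in patterns:
        mol = make_ring_fixture(pattern, identifier=name)
        write_xyz(mol, out_dir / "structures" / f"{name}.xyz")
        classes = enumerate_sites(mol)
        if not classes:
            continue
        redox = float(rng.normal(*config.redox_distribution))
        mol_rows.append({"arene_id": name, "redox_potential": redox})
        scores: dict[str, float] = {}
        mults: dict[str, int] = {}
        for cls in classes:
            values = _sample_site(rng, config.distributions)
            g = sum(w * values[k] for k, w in elec_weights.items())
            g += config.redox_coupling * redox * values["fukui_minus"]
            scores[cls.label] = g
            mults[cls.label] = cls.multiplicity
            for atom in cls.atom_indices:
                site_rows.append({
                    "arene_id": name, "atom_index": atom,
                    **{k: values[k] for k in (
                        "fukui_plus", "fukui_minus", "fukui_zero",
                        "partial_charge", "ch_bde", "ext_1", "ext_2", "ext_3")},
                })
        sp = site_probabilities(scores, mults, config.temperature, arene_id=name)
        for lab, frac in sp.probabilities.items():
            meas_rows.append({
                "arene_id": name, "class_label": lab, "fraction": frac,
                "multiplicity": mults[lab],
                "temperature_K": config.temperature,
            })

    paths = {
        "structures": out_dir / "structures",
        "qm_sites": out_dir / "qm_sites.csv",
        "qm_molecules": out_dir / "qm_molecules.csv",
        "measurements": out_dir / "measurements.csv",
    }
    pd.DataFrame(site_rows).to_csv(paths["qm_sites"], index=False)
    pd.DataFrame(mol_rows).to_csv(paths["qm_molecules"], index=False)
    pd.DataFrame(meas_rows).to_csv(paths["measurements"], index=False)
    return paths
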