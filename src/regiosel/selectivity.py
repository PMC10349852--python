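"""Selectivity thermodynamics: isomer ratios, DDG targets, site probabilities.

An observed isomer ratio between two competing C-H positions reflects both
an intrinsic per-site preference and a statistical factor (the number of
symmetry-equivalent positions in each class).  With product fractions p_a,
p_b and multiplicities m_a, m_b, the apparent free-energy preference of
site A over site B is

    DDG_app = R * T * ln[ (p_a / m_a) / (p_b / m_b) ]   [kcal/mol]

with R = 1.9872e-3 kcal mol^-1 K^-1.  Positive DDG_app means site A is
favored per individual C-H position.  This statistical-factor-corrected
energy, at the measurement temperature, is the regression target of the
selectivity model; it is exactly antisymmetric under pair swap.

Pairwise model predictions are reduced to one score per site by
least-squares "potential" fitting on the pair-comparison graph
(Bradley-Terry style), and scores map back to an isomer distribution via a
multiplicity-weighted Boltzmann factor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

__all__ = [
    "GAS_CONSTANT_KCAL",
    "SelectivityMeasurement",
    "PairTarget",
    "SiteProbability",
    "aggregate_site_scores",
    "ddg_to_ratio",
    "measurement_to_pair_targets",
    "parse_ratio",
    "ratio_to_ddg",
    "site_probabilities",
]

GAS_CONSTANT_KCAL = 1.9872e-3  # kcal mol^-1 K^-1


@dataclass
class SelectivityMeasurement:
    """Observed isomer distribution over symmetry classes of one arene.

    Fractions are normalized over the *measured* classes (unmeasured minor
    isomers are simply absent); multiplicities are the class sizes from site
    enumeration.
    """

    arene_id: str
    fractions: dict[str, float]        # class label -> product fraction
    multiplicities: dict[str, int]     # class label -> statistical factor
    temperature: float                 # K

    def __post_init__(self) -> None:
        if self.temperature <= 0:
            raise ValueError("temperature must be positive (K)")
        if set(self.fractions) != set(self.multiplicities):
            raise ValueError(
                f"{self.arene_id}: fraction/multiplicity class labels differ"
            )
        if any(f < 0 for f in self.fractions.values()):
            raise ValueError(f"{self.arene_id}: negative fraction")
        total = sum(self.fractions.values())
        if not math.isclose(total, 1.0, rel_tol=0, abs_tol=1e-6):
            raise ValueError(f"{self.arene_id}: fractions sum to {total}, not 1")
        if any(m < 1 for m in self.multiplicities.values()):
            raise ValueError(f"{self.arene_id}: multiplicity < 1")


@dataclass(frozen=True)
class PairTarget:
    """Apparent per-site free-energy preference of site A over B (kcal/mol)."""

    arene_id: str
    class_a: str
    class_b: str
    ddg_app: float

    def __post_init__(self) -> None:
        if not np.isfinite(self.ddg_app):
            raise ValueError("non-finite pair target")


@dataclass
class SiteProbability:
    """Predicted isomer distribution over site classes."""

    arene_id: str
    probabilities: dict[str, float]
    temperature: float

    def __post_init__(self) -> None:
        vals = np.array(list(self.probabilities.values()))
        if np.any(vals < -1e-12) or not math.isclose(vals.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("probabilities must be in [0,1] and sum to 1")


def parse_ratio(text: str) -> list[float]:
    """Parse an isomer-ratio string like ``"17:1"`` into fractions.

    Components are separated by ``:``; the result is normalized to sum to 1.
    """
    parts = [float(p) for p in str(text).split(":")]
    if len(parts) < 2 or any(p < 0 for p in parts) or sum(parts) == 0:
        raise ValueError(f"cannot parse ratio {text!r}")
    total = sum(parts)
    return [p / total for p in parts]


def ratio_to_ddg(
    fraction_a: float,
    fraction_b: float,
    mult_a: int = 1,
    mult_b: int = 1,
    temperature: float = 298.15,
) -> float:
    """Statistical-factor-corrected DDG of site A over site B in kcal/mol.

    ``DDG = R*T*ln[(fraction_a/mult_a) / (fraction_b/mult_b)]``; positive
    means site A is favored per site.  Zero fractions are rejected (clamp
    tiny observed fractions to a detection-limit epsilon upstream if a minor
    isomer was not observed at all).
    """
    if fraction_a <= 0 or fraction_b <= 0:
        raise ValueError(
            "fractions must be strictly positive; clamp unobserved isomers "
            "to a detection-limit epsilon before conversion"
        )
    if mult_a < 1 or mult_b < 1:
        raise ValueError("multiplicities must be >= 1")
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    return GAS_CONSTANT_KCAL * temperature * math.log(
        (fraction_a / mult_a) / (fraction_b / mult_b)
    )


def ddg_to_ratio(
    ddg: float,
    mult_a: int = 1,
    mult_b: int = 1,
    temperature: float = 298.15,
) -> tuple[float, float]:
    """Inverse of :func:`ratio_to_ddg`: normalized fraction pair (A, B)."""
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    if mult_a < 1 or mult_b < 1:
        raise ValueError("multiplicities must be >= 1")
    # weight per class = multiplicity * per-site Boltzmann factor
    x = ddg / (GAS_CONSTANT_KCAL * temperature)
    # stable normalization for large |x|
    wa = mult_a * math.exp(min(x, 0.0))
    wb = mult_b * math.exp(min(-x, 0.0))
    total = wa + wb
    return wa / total, wb / total


def measurement_to_pair_targets(m: SelectivityMeasurement) -> list[PairTarget]:
    """All pairwise DDG targets from one isomer distribution.

    Classes are paired in lexicographic label order (A before B), so the
    targets follow the canonical pair orientation.
    """
    labels = sorted(m.fractions)
    out: list[PairTarget] = []
    for i, la in enumerate(labels):
        for lb in labels[i + 1:]:
            out.append(PairTarget(
                arene_id=m.arene_id,
                class_a=la,
                class_b=lb,
                ddg_app=ratio_to_ddg(
                    m.fractions[la], m.fractions[lb],
                    m.multiplicities[la], m.multiplicities[lb],
                    m.temperature,
                ),
            ))
    return out


def aggregate_site_scores(
    pairwise: Sequence[tuple[str, str, float]],
) -> dict[str, float]:
    """Least-squares site potentials from pairwise DDG predictions.

    Given predictions ``(site_a, site_b, ddg_ab)``, finds per-site scores
    ``g`` minimizing ``sum (g_a - g_b - ddg_ab)^2`` with the zero-sum gauge
    ``sum g = 0``.  Unique whenever the comparison graph is connected; a
    disconnected graph is an error naming the components.  On a spanning
    tree of consistent comparisons the input DDGs are reproduced exactly.
    """
    if not pairwise:
        raise ValueError("no pairwise predictions")
    g = nx.Graph()
    for a, b, _ in pairwise:
        g.add_edge(a, b)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        raise ValueError(
            "comparison graph is disconnected; components: "
            + "; ".join(str(sorted(c)) for c in comps)
        )
    sites = sorted(g.nodes)
    idx = {s: k for k, s in enumerate(sites)}
    n = len(sites)
    rows = np.zeros((len(pairwise) + 1, n))
    rhs = np.zeros(len(pairwise) + 1)
    for r, (a, b, ddg) in enumerate(pairwise):
        rows[r, idx[a]] = 1.0
        rows[r, idx[b]] = -1.0
        rhs[r] = ddg
    rows[-1, :] = 1.0  # zero-sum gauge
    sol, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
    sol = sol - sol.mean()  # enforce gauge exactly
    return {s: float(sol[idx[s]]) for s in sites}


def site_probabilities(
    scores: Mapping[str, float],
    multiplicities: Mapping[str, int],
    temperature: float,
    arene_id: str = "",
) -> SiteProbability:
    """Multiplicity-weighted Boltzmann distribution over site classes.

    ``p_i ~ mult_i * exp(g_i / (R*T))`` — higher score means more favored.
    """
    if temperature <= 0:
        raise ValueError("temperature must be positive (K)")
    labels = sorted(scores)
    g = np.array([scores[l] for l in labels], dtype=float)
    if not np.all(np.isfinite(g)):
        raise ValueError("non-finite site scores")
    m = np.array([multiplicities[l] for l in labels], dtype=float)
    x = g / (GAS_CONSTANT_KCAL * temperature)
    w = m * np.exp(x - x.max())
    p = w / w.sum()
    return SiteProbability(
        arene_id=arene_id,
        probabilities={l: float(pi) for l, pi in zip(labels, p)},
        temperature=temperature,
    )
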