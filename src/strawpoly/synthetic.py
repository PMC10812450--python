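"""Synthetic study generator: known second-order surfaces over the
2-area × 7-date sampling design plus Gaussian noise.

Defaults reproduce the study conditions: the 28 harvest conditions of the
transcribed sampling plan, true coefficients taken from the published
coefficient table, and per-response noise SDs equal to the published
RMSE row — so synthetic fits land in the same fit-quality regime the
study reports.  An optional smooth non-polynomial distortion
(amplitude · sin(π·X5) · X1) lets tests create surfaces a second-order
polynomial cannot represent.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datamodel import (
    AREAS,
    INFECTION_CLASS_MIDPOINT,
    RESPONSE_COLUMNS,
    VARIETIES,
    SampleCondition,
    load_conditions,
)
from .rsm import TERMS, FactorCoding, build_design_matrix
from . import rsm as _rsm

__all__ = ["SimulationSpec", "generate_design", "simulate_responses", "inject_missingness"]

#: Published per-response fit RMSEs, used as default noise SDs.
DEFAULT_NOISE_SD = {
    "hydroxybenzoic": 7.455,
    "hydroxycinnamic": 38.418,
    "flavones": 8.948,
    "abts_ic50": 0.04,
    "dpph_ic50": 0.12,
}

#: High/low borer-infection ranges (%) from the sampling plan.
INFECTION_RANGES = {"high": (4.0, 11.0), "low": (0.0, 4.0)}


def _default_true_beta() -> dict[str, np.ndarray]:
    fixture = _rsm.load_coefficient_fixture()
    out = {}
    for resp, col in (
        ("hydroxybenzoic", "hydroxybenzoic"),
        ("hydroxycinnamic", "hydroxycinnamic"),
        ("flavones", "flavones"),
        ("abts_ic50", "abts"),
        ("dpph_ic50", "dpph"),
    ):
        out[resp] = _rsm.model_from_coefficients(col, fixture).beta
    return out


@dataclass
class SimulationSpec:
    """Design levels, true surface coefficients and noise for a run."""

    seed: int
    dates: list[_dt.date] | None = None
    varieties: list[str] | None = None
    areas: list[str] | None = None
    infection_classes: tuple[str, ...] = ("high", "low")
    replicates: int = 1
    true_beta: dict[str, np.ndarray] | None = None  # per response, len-20
    noise_sd: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_NOISE_SD))
    distortion_amplitude: float = 0.0

    def __post_init__(self):
        if any(sd < 0 for sd in self.noise_sd.values()):
            raise ValueError("noise SD must be >= 0")
        if self.true_beta is not None:
            for resp, beta in self.true_beta.items():
                if len(beta) != len(TERMS):
                    raise ValueError(f"{resp}: coefficient vector must have {len(TERMS)} terms")

    def resolve_beta(self) -> dict[str, np.ndarray]:
        return _default_true_beta() if self.true_beta is None else self.true_beta


def generate_design(spec: SimulationSpec) -> list[SampleCondition]:
    """Deterministic sampling design (responses, not the design, are random).

    With default level lists this returns the 28 study conditions.
    Custom levels build area × date × infection-class combinations with a
    cyclic variety/harvest assignment and within-class infection levels
    spread evenly over the stated high/low ranges.
    """
    custom = not (spec.dates is None and spec.varieties is None and spec.areas is None)
    if not custom:
        base, _ = load_conditions()
        # the published tables record only the infection *class*; each real
        # batch had its own precise level, so spread levels evenly over the
        # stated class ranges (keeps the infection quadratic identifiable)
        counts = {
            icls: sum(1 for c in base if c.infection_class == icls)
            for icls in ("high", "low")
        }
        seen = {"high": 0, "low": 0}
        levels = {}
        for c in base:
            lo, hi = INFECTION_RANGES[c.infection_class]
            m = counts[c.infection_class]
            levels[c.sample_id] = lo + (hi - lo) * (
                seen[c.infection_class] / max(m - 1, 1)
            )
            seen[c.infection_class] += 1
        conditions = []
        for rep in range(spec.replicates):
            for c in base:
                sid = c.sample_id if spec.replicates == 1 else f"{c.sample_id}r{rep + 1}"
                conditions.append(
                    SampleCondition(
                        sample_id=sid, area=c.area, collection_date=c.collection_date,
                        variety=c.variety, infection_level=levels[c.sample_id],
                        infection_class=c.infection_class,
                        harvest_number=c.harvest_number,
                    )
                )
        return conditions

    dates = (
        sorted({c.collection_date for c in load_conditions()[0]})
        if spec.dates is None else spec.dates
    )
    varieties = list(VARIETIES) if spec.varieties is None else spec.varieties
    areas = list(AREAS) if spec.areas is None else spec.areas
    if not dates or not varieties or not areas or not spec.infection_classes:
        raise ValueError("every level list must be nonempty")
    combos = [
        (a, d, icls)
        for a in areas
        for d in dates
        for icls in spec.infection_classes
    ]
    per_class = {icls: sum(1 for c in combos if c[2] == icls) for icls in spec.infection_classes}
    seen = {icls: 0 for icls in spec.infection_classes}
    conditions = []
    for rep in range(spec.replicates):
        seen = {icls: 0 for icls in spec.infection_classes}
        for k, (area, date, icls) in enumerate(combos):
            lo, hi = INFECTION_RANGES.get(icls, (0.0, 10.0))
            m = per_class[icls]
            level = lo + (hi - lo) * (seen[icls] / max(m - 1, 1))
            seen[icls] += 1
            conditions.append(
                SampleCondition(
                    sample_id=f"S{rep * len(combos) + k + 1:03d}",
                    area=area,
                    collection_date=date,
                    variety=varieties[(2 * k + rep) % len(varieties)],
                    infection_level=level,
                    infection_class=icls if icls in ("high", "low") else "low",
                    harvest_number=1 + (3 * k + rep) % 7,
                )
            )
    return conditions


def simulate_responses(
    design: list[SampleCondition],
    spec: SimulationSpec,
    coding: FactorCoding | None = None,
) -> pd.DataFrame:
    """Draw y = polynomial(coded x; true β) + N(0, σ) (+ distortion).

    Returns a response table (sample_id index, RESPONSE_COLUMNS) matching
    the aggregation output schema.  Reproducible from spec.seed.
    """
    coding = FactorCoding.from_conditions(design) if coding is None else coding
    coded = coding.code_all(design)
    X = build_design_matrix(coded)
    beta = spec.resolve_beta()
    rng = np.random.default_rng(spec.seed)
    table = pd.DataFrame(
        index=pd.Index([c.sample_id for c in design], name="sample_id"),
        columns=list(RESPONSE_COLUMNS), dtype=float,
    )
    distort = spec.distortion_amplitude * np.sin(np.pi * coded[:, 4]) * coded[:, 0]
    for resp in RESPONSE_COLUMNS:
        mu = X @ beta[resp]
        sd = spec.noise_sd.get(resp, 0.0)
        noise = rng.normal(0.0, sd, size=len(design)) if sd > 0 else 0.0
        table[resp] = mu + noise + distort
    return table


def inject_missingness(
    table: pd.DataFrame, pattern: list[tuple[str, str]]
) -> pd.DataFrame:
    """Flag (sample_id, response) cells as missing (NaN), e.g. to mirror
    the not-determined antioxidant assays.

    Unknown sample ids or responses raise KeyError; everything outside the
    pattern is untouched.
    """
    out = table.copy()
    for sample_id, response in pattern:
        if sample_id not in out.index:
            raise KeyError(f"unknown sample {sample_id!r}")
        if response not in out.columns:
            raise KeyError(f"unknown response {response!r}")
        out.loc[sample_id, response] = float("nan")
    return out
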