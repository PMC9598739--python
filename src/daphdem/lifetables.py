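"""Abbreviated cohort life tables and individual life-history traits.

A life table for one treatment holds the age-specific survivorship l_x
(fraction of the starting cohort alive through day x) and fertility m_x
(neonates born on day x per female alive on day x).  The product l_x * m_x is
then the expected number of births on day x per *initial* female, the
quantity the Euler-Lotka equation discounts.

Also provides the two descriptive calcium thresholds used to summarise a Ca
gradient: the survival threshold (bracket between the highest Ca level with
>50% mortality and no reproduction, and the lowest level above it escaping
that fate) and the reproductive saturation point (lowest Ca whose
reproduction output no longer differs from every higher level).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .simulate import IndividualRecord

__all__ = [
    "LifeTable",
    "TraitSummary",
    "ThresholdBracket",
    "build_life_table",
    "extract_traits",
    "traits_table",
    "survival_threshold_bracket",
    "reproduction_saturation_point",
    "life_table_frame",
]


@dataclass(frozen=True)
class LifeTable:
    """Age-indexed survivorship and fertility schedules for one cohort.

    ``alive[x]`` counts females alive through day x (x = 0..horizon), and
    ``births[x]`` counts neonates released on day x.  ``l_x = alive/n0`` and
    ``m_x = births/alive`` (0 where nobody is alive).  A female found dead at
    the day-x census contributes to ``alive`` up to day x-1 only; censored
    females count as alive through the horizon.
    """

    ages: np.ndarray     # 0..horizon
    alive: np.ndarray    # integer counts
    births: np.ndarray   # integer counts
    n0: int

    @property
    def l_x(self) -> np.ndarray:
        return self.alive / self.n0

    @property
    def m_x(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            m = np.where(self.alive > 0, self.births / np.maximum(self.alive, 1), 0.0)
        return m

    @property
    def horizon(self) -> int:
        return int(self.ages[-1])

    def net_reproduction(self) -> float:
        """Sum of l_x * m_x: expected lifetime offspring per initial female."""
        return float(np.sum(self.l_x * self.m_x))

    def total_offspring(self) -> int:
        return int(self.births.sum())


def build_life_table(records: Sequence[IndividualRecord],
                     horizon: Optional[int] = None) -> LifeTable:
    """Build the abbreviated life table for one treatment's records.

    All records must share the same (ca, food, temp) treatment cell.
    """
    records = list(records)
    if not records:
        raise ValueError("cannot build a life table from zero records")
    keys = {r.treatment.key() for r in records}
    if len(keys) > 1:
        raise ValueError(f"records mix treatments: {sorted(keys)}")
    if horizon is None:
        horizon = max(r.death_day for r in records)
        horizon = max(horizon, max((d for r in records for d, _ in r.clutches),
                                   default=horizon))

    n0 = len(records)
    ages = np.arange(horizon + 1)
    alive = np.zeros(horizon + 1, dtype=int)
    births = np.zeros(horizon + 1, dtype=int)
    for r in records:
        last_alive = r.death_day if r.censored else r.death_day - 1
        alive[: min(last_alive, horizon) + 1] += 1
        for day, n in r.clutches:
            if day <= horizon:
                births[day] += n
    return LifeTable(ages=ages, alive=alive, births=births, n0=n0)


def life_table_frame(table: LifeTable) -> pd.DataFrame:
    """Tabular form: columns x, n_alive, l_x, births, m_x."""
    return pd.DataFrame({
        "x": table.ages,
        "n_alive": table.alive,
        "l_x": table.l_x,
        "births": table.births,
        "m_x": table.m_x,
    })


@dataclass(frozen=True)
class TraitSummary:
    """Individual-level life-history traits."""

    individual_id: str
    age_at_maturity: Optional[int]
    moulting_rate: Optional[float]   # juvenile moults per day up to maturity
    reproduction_output: int         # total neonates over the experiment
    brood_size: Optional[float]      # mean neonates per clutch
    lifespan: int
    censored: bool
    body_size: Optional[float]


def extract_traits(record: IndividualRecord) -> TraitSummary:
    """Compute the standard traits from one record.

    The moulting rate of juveniles is the number of moults accumulated up to
    (and including) the maturation moult divided by the age at maturity.
    """
    maturity = record.maturity_day
    moulting_rate = None
    if maturity is not None:
        n_juvenile_moults = sum(1 for d in record.moult_days if d <= maturity)
        moulting_rate = n_juvenile_moults / maturity
        if record.moult_days and record.clutches:
            first_clutch = min(d for d, _ in record.clutches)
            if first_clutch < min(record.moult_days):
                warnings.warn(
                    f"{record.individual_id}: clutch on day {first_clutch} "
                    "precedes the first recorded moult", stacklevel=2)
    n_clutches = len(record.clutches)
    brood = (record.total_offspring() / n_clutches) if n_clutches else None
    return TraitSummary(
        individual_id=record.individual_id,
        age_at_maturity=maturity,
        moulting_rate=moulting_rate,
        reproduction_output=record.total_offspring(),
        brood_size=brood,
        lifespan=record.death_day,
        censored=record.censored,
        body_size=record.body_size,
    )


def traits_table(records: Sequence[IndividualRecord]) -> pd.DataFrame:
    """Traits for many records, with treatment covariates attached."""
    rows = []
    for r in records:
        t = extract_traits(r)
        rows.append({
            "individual_id": t.individual_id,
            "ca": r.treatment.ca,
            "food": r.treatment.food,
            "temp": r.treatment.temp,
            "box_id": r.treatment.box_id,
            "age_at_maturity": t.age_at_maturity,
            "moulting_rate": t.moulting_rate,
            "reproduction_output": t.reproduction_output,
            "brood_size": t.brood_size,
            "lifespan": t.lifespan,
            "censored": int(t.censored),
            "body_size": t.body_size,
        })
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ThresholdBracket:
    """A Ca interval bracketing where a criterion flips along the gradient.

    ``lower`` is the highest Ca level failing the criterion and ``upper`` the
    lowest observed level above it that passes.  Edge sentinels: lower = 0
    when no level fails; upper = inf when no level passes.  ``ambiguous`` is
    set when pass/fail is not monotone along the gradient (the innermost
    bracket is then reported).
    """

    lower: float
    upper: float
    criterion: str
    ambiguous: bool = False


def survival_threshold_bracket(
        summaries: Mapping[float, tuple[float, bool]],
        criterion: str = "survival") -> ThresholdBracket:
    """Bracket the Ca survival threshold along a gradient.

    Parameters
    ----------
    summaries : mapping
        ``{ca: (survival_fraction, any_reproduction)}`` for one food x
        temperature combination, over >= 2 Ca levels.  A level *fails* when
        mortality over the experimental period exceeds 50% (survival fraction
        strictly below 0.5; a tie at exactly 50% counts as surviving) *and*
        no female reproduced.
    """
    if len(summaries) < 2:
        raise ValueError("need at least two Ca levels to bracket a threshold")
    levels = sorted(summaries)
    fails = [summaries[ca][0] < 0.5 and not summaries[ca][1] for ca in levels]

    if not any(fails):
        return ThresholdBracket(0.0, levels[0], criterion)
    if all(fails):
        return ThresholdBracket(levels[-1], math.inf, criterion)

    highest_fail_idx = max(i for i, f in enumerate(fails) if f)
    passing_above = [i for i in range(highest_fail_idx + 1, len(levels))
                     if not fails[i]]
    if not passing_above:  # highest level fails
        return ThresholdBracket(levels[-1], math.inf, criterion,
                                ambiguous=not _monotone(fails))
    upper_idx = min(passing_above)
    return ThresholdBracket(levels[highest_fail_idx], levels[upper_idx],
                            criterion, ambiguous=not _monotone(fails))


def _monotone(fails: Sequence[bool]) -> bool:
    """True when the fail pattern is a prefix (fail...fail, pass...pass)."""
    seen_pass = False
    for f in fails:
        if not f:
            seen_pass = True
        elif seen_pass:
            return False
    return True


def reproduction_saturation_point(
        outputs: Mapping[float, Sequence[float]],
        alpha: float = 0.05,
        n_permutations: int = 3000,
        seed: int = 0) -> Optional[float]:
    """Lowest Ca level whose reproduction matches every higher level.

    Uses a two-sided two-sample permutation test on the difference in mean
    reproduction output (see :func:`daphdem.inference.permutation_two_sample`).
    Returns None when no level saturates, or when reproduction is zero
    everywhere (no signal to compare).
    """
    from .inference import permutation_two_sample

    if len(outputs) < 2:
        raise ValueError("need at least two Ca levels")
    levels = sorted(outputs)
    arrays = {ca: np.asarray(outputs[ca], dtype=float) for ca in levels}
    if all(np.all(a == 0) for a in arrays.values()):
        warnings.warn("reproduction is zero at every Ca level; "
                      "saturation point undefined", stacklevel=2)
        return None
    rng_seed = seed
    for i, ca in enumerate(levels[:-1]):
        saturated = True
        for higher in levels[i + 1:]:
            p = permutation_two_sample(arrays[ca], arrays[higher],
                                       n_permutations=n_permutations,
                                       seed=rng_seed)
            rng_seed += 1
            if p < alpha:
                saturated = False
                break
        if saturated:
            return ca
    return None
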