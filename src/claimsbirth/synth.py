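"""Synthetic administrative-claims generator with known ground truth.

No public claims extract with mother-child linkage exists, so validation
and testing run against simulated data that reproduces the statistical
structure the pipeline assumes:

* a cohort of insured women, each with a birth month and a
  husband-identifiable flag; a configurable fraction experiences at least
  one live birth in the observation window, with maternal age drawn from a
  realistic five-year-band distribution (defaults mirror a Japanese
  insured-population cohort: mode at 30-34, ~4.4% of women giving birth);
* every live birth creates a parent-child link (stillbirths and abortions
  are out of scope and never linked);
* a birth emits claims only if it is not "silent": uncomplicated normal
  vaginal deliveries are typically not covered by medical insurance and
  leave no claim at all, which bounds achievable claims-based sensitivity;
* non-silent births emit procedure/medication/diagnosis lines
  independently, billed in the birth month or (with the discharge-shift
  probability) one month later; diagnosis codes additionally "echo" at
  prenatal visits up to nine months before and postpartum checks up to a
  few months after the birth, and each diagnosis line may carry a suspected
  (provisional/rule-out) flag;
* second births follow after a truncated-normal inter-birth gap (default
  mean 24 months — the typical two-year sibling spacing);
* non-birthing women emit low-rate childbirth-set diagnosis noise
  (rule-out workups), with the suspected-flag probability doubled.

Because domains are emitted independently, per-algorithm sensitivity has a
closed form (:func:`expected_sensitivity`) usable as an oracle in
parameter-recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .algorithms import AlgorithmSpec, Condition
from .codesets import CodeSets, default_codesets
from .errors import ConfigError, UnsupportedOracleError
from .io import write_claims, write_links, write_population
from .months import parse_ym

__all__ = ["SynthConfig", "SyntheticDataset", "generate", "expected_sensitivity"]

#: Maternal age bands (completed years at birth) and default weights.
DEFAULT_AGE_BANDS: tuple[tuple[int, int, float], ...] = (
    (15, 19, 0.010),
    (20, 24, 0.086),
    (25, 29, 0.241),
    (30, 34, 0.347),
    (35, 39, 0.247),
    (40, 44, 0.066),
    (45, 49, 0.003),
)


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters; defaults are the reference study conditions."""

    n_women: int = 100_000
    p_husband_identified: float = 1.0
    age_bands: tuple[tuple[int, int, float], ...] = DEFAULT_AGE_BANDS
    birth_rate: float = 0.044
    p_second_birth: float = 0.30
    gap_mean: float = 24.0
    gap_sd: float = 6.0
    gap_min: int = 10
    p_silent_birth: float = 0.30
    p_proc: float = 0.50
    p_med: float = 0.55
    p_dx: float = 0.80
    p_suspected: float = 0.10
    p_discharge_shift: float = 0.30
    echo_prepartum: float = 0.20
    echo_postpartum: tuple[tuple[int, float], ...] = ((1, 0.12), (2, 0.05), (3, 0.03))
    fp_rate: float = 1e-4
    window_start: str = "2014-04"
    window_end: str = "2023-02"
    seed: int = 0

    def __post_init__(self):
        probs = {
            "p_husband_identified": self.p_husband_identified,
            "birth_rate": self.birth_rate,
            "p_second_birth": self.p_second_birth,
            "p_silent_birth": self.p_silent_birth,
            "p_proc": self.p_proc,
            "p_med": self.p_med,
            "p_dx": self.p_dx,
            "p_suspected": self.p_suspected,
            "p_discharge_shift": self.p_discharge_shift,
            "echo_prepartum": self.echo_prepartum,
            "fp_rate": self.fp_rate,
        }
        for name, p in probs.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be a probability, got {p}")
        for off, p in self.echo_postpartum:
            if off < 1 or not 0.0 <= p <= 1.0:
                raise ConfigError(f"bad postpartum echo entry ({off}, {p})")
        w = sum(b[2] for b in self.age_bands)
        if abs(w - 1.0) > 1e-6:
            raise ConfigError(f"age band weights sum to {w}, expected 1")
        if self.n_women < 1:
            raise ConfigError("n_women must be positive")
        if self.gap_min < 1 or self.gap_sd < 0:
            raise ConfigError("invalid inter-birth gap parameters")
        if self.window[1] <= self.window[0]:
            raise ConfigError("empty observation window")
        if self.p_second_birth > 0 and self.window[1] - self.window[0] <= self.gap_min:
            raise ConfigError("window too short for any second birth")

    @property
    def window(self) -> tuple[int, int]:
        return (parse_ym(self.window_start), parse_ym(self.window_end))

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_bands"] = [list(b) for b in self.age_bands]
        d["echo_postpartum"] = [list(e) for e in self.echo_postpartum]
        return d


@dataclass
class SyntheticDataset:
    """Generated tables plus the per-birth ground truth."""

    population: pd.DataFrame
    links: pd.DataFrame
    claims: pd.DataFrame
    truth: pd.DataFrame
    config: SynthConfig

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_population(self.population, out / "population.csv")
        write_links(self.links, out / "links.csv")
        write_claims(self.claims, out / "claims.csv")
        t = self.truth.copy()
        t["year"] = t["birth_month_idx"] // 12
        t["month"] = t["birth_month_idx"] % 12 + 1
        t[["woman_id", "birth_number", "year", "month", "silent"]].assign(
            silent=lambda d: d["silent"].astype(int)
        ).to_csv(out / "truth.csv", index=False)
        (out / "synth_config.yaml").write_text(
            yaml.safe_dump(self.config.to_dict(), sort_keys=False)
        )


def generate(config: SynthConfig, cs: CodeSets | None = None) -> SyntheticDataset:
    """Draw one synthetic dataset; byte-identical for identical config."""
    cs = cs or default_codesets()
    rng = np.random.default_rng(config.seed)
    start, end = config.window
    n_months = end - start
    n = config.n_women
    ids = np.array([f"W{i:06d}" for i in range(n)])

    has_birth = rng.random(n) < config.birth_rate
    nb = int(has_birth.sum())
    birth_ids = ids[has_birth]

    # first births and maternal ages
    first = rng.integers(start, end, nb)
    weights = np.array([b[2] for b in config.age_bands])
    band = rng.choice(len(config.age_bands), size=nb, p=weights / weights.sum())
    lo = np.array([b[0] for b in config.age_bands])[band]
    age_years = lo + rng.integers(0, 5, nb)
    mother_birth_pos = first - age_years * 12 - rng.integers(0, 12, nb)

    # second births after a truncated-normal gap
    wants_second = rng.random(nb) < config.p_second_birth
    gap = np.round(rng.normal(config.gap_mean, config.gap_sd, nb)).astype(np.int64)
    gap = np.maximum(gap, config.gap_min)
    second = first + gap
    has_second = wants_second & (second < end)

    # non-birthing women: broad insured-population age range at window start
    n_rest = n - nb
    rest_age = rng.integers(15, 70, n_rest)
    mother_birth_rest = start - rest_age * 12 - rng.integers(0, 12, n_rest)

    birth_month_idx = np.empty(n, dtype=np.int64)
    birth_month_idx[has_birth] = mother_birth_pos
    birth_month_idx[~has_birth] = mother_birth_rest
    husband = rng.random(n) < config.p_husband_identified

    population = pd.DataFrame(
        {"birth_month_idx": birth_month_idx, "husband_identified": husband},
        index=pd.Index(ids, name="woman_id"),
    )

    # one truth row + one link per live birth
    b_wids = np.concatenate([birth_ids, birth_ids[has_second]])
    b_months = np.concatenate([first, second[has_second]])
    b_number = np.concatenate(
        [np.ones(nb, dtype=np.int64), np.full(int(has_second.sum()), 2, dtype=np.int64)]
    )
    order = np.lexsort((b_number, b_wids))
    b_wids, b_months, b_number = b_wids[order], b_months[order], b_number[order]

    n_births = len(b_wids)
    silent = rng.random(n_births) < config.p_silent_birth
    shift = rng.random(n_births) < config.p_discharge_shift
    m0 = b_months + shift.astype(np.int64)

    links = pd.DataFrame({"mother_id": b_wids, "child_birth_month_idx": b_months})
    truth = pd.DataFrame(
        {
            "woman_id": b_wids,
            "birth_number": b_number,
            "birth_month_idx": b_months,
            "silent": silent,
        }
    )

    # claims emission
    diag_codes = np.array(sorted(cs.diagnosis))
    proc_codes = np.array(sorted(cs.procedure))
    med_codes = np.array(sorted(cs.medication))
    parts: list[pd.DataFrame] = []

    def emit(wids, months, domain, codes, suspected):
        parts.append(
            pd.DataFrame(
                {
                    "woman_id": wids,
                    "month_idx": months,
                    "domain": domain,
                    "code": codes,
                    "suspected": suspected,
                }
            )
        )

    active = ~silent
    m_proc = active & (rng.random(n_births) < config.p_proc)
    emit(
        b_wids[m_proc],
        m0[m_proc],
        "procedure",
        rng.choice(proc_codes, int(m_proc.sum())),
        np.zeros(int(m_proc.sum()), dtype=bool),
    )
    m_med = active & (rng.random(n_births) < config.p_med)
    emit(
        b_wids[m_med],
        m0[m_med],
        "medication",
        rng.choice(med_codes, int(m_med.sum())),
        np.zeros(int(m_med.sum()), dtype=bool),
    )
    m_dx = active & (rng.random(n_births) < config.p_dx)
    emit(
        b_wids[m_dx],
        m0[m_dx],
        "diagnosis",
        rng.choice(diag_codes, int(m_dx.sum())),
        rng.random(int(m_dx.sum())) < config.p_suspected,
    )
    # diagnosis echoes: prenatal visits and postpartum checks
    echo_offsets = [(off, config.echo_prepartum) for off in range(-9, 0)]
    echo_offsets += [(int(off), p) for off, p in config.echo_postpartum]
    for off, p in echo_offsets:
        if p == 0:
            continue
        m = m_dx & (rng.random(n_births) < p)
        k = int(m.sum())
        emit(
            b_wids[m],
            b_months[m] + off,
            "diagnosis",
            rng.choice(diag_codes, k),
            rng.random(k) < config.p_suspected,
        )

    # childbirth-code noise among non-birthing women (rule-out workups)
    rest_ids = ids[~has_birth]
    if config.fp_rate > 0 and n_rest > 0:
        counts = rng.binomial(n_months, config.fp_rate, n_rest)
        total = int(counts.sum())
        wids = np.repeat(rest_ids, counts)
        months = start + rng.integers(0, n_months, total)
        emit(
            wids,
            months,
            "diagnosis",
            rng.choice(diag_codes, total),
            rng.random(total) < min(1.0, 2 * config.p_suspected),
        )

    claims = pd.concat(parts, ignore_index=True)
    claims = claims[(claims["month_idx"] >= start) & (claims["month_idx"] < end)]
    claims = claims.sort_values(
        ["woman_id", "month_idx", "domain", "code"], kind="mergesort"
    ).reset_index(drop=True)
    return SyntheticDataset(
        population=population, links=links, claims=claims, truth=truth, config=config
    )


# -- closed-form sensitivity oracle ----------------------------------------

_ORACLE_TRUTH = {
    Condition.A_SUSP: "dx",
    Condition.A: "dx",
    Condition.B: "proc",
    Condition.C: "med",
}


def expected_sensitivity(config: SynthConfig, spec: AlgorithmSpec) -> float:
    """Analytic detection-with-correct-dating probability per birthing woman.

    Valid under independent-domain emission with a single birth per woman
    and postpartum diagnosis echoes confined to the one-month matching
    tolerance; then every detected woman is also correctly dated and the
    sensitivity is the inclusion-exclusion probability that the Boolean
    expression is satisfied, times the non-silent probability.

    Raises :class:`UnsupportedOracleError` outside that regime (second
    births, echoes beyond +1, preterm-excluded conditions, or [A] with a
    non-zero suspected-flag rate — these need record-level enumeration).
    """
    if config.p_second_birth > 0:
        raise UnsupportedOracleError("oracle requires p_second_birth = 0")
    for off, p in config.echo_postpartum:
        if p > 0 and off > 1:
            raise UnsupportedOracleError(
                "oracle requires postpartum echoes within the +1 matching window"
            )
    refs = spec.expression.conditions()
    if refs & {Condition.A_PRE, Condition.A_PRE_SUSP}:
        raise UnsupportedOracleError("preterm-excluded conditions are not covered")
    if Condition.A in refs and config.p_suspected > 0:
        raise UnsupportedOracleError("[A] requires p_suspected = 0")

    p = {"dx": config.p_dx, "proc": config.p_proc, "med": config.p_med}
    total = 0.0
    for dx in (0, 1):
        for proc in (0, 1):
            for med in (0, 1):
                present = {"dx": dx, "proc": proc, "med": med}
                truth = {c: bool(present[d]) for c, d in _ORACLE_TRUTH.items()}
                truth[Condition.A_PRE] = truth[Condition.A]
                truth[Condition.A_PRE_SUSP] = truth[Condition.A_SUSP]
                if spec.expression.evaluate(truth):
                    w = 1.0
                    for d in ("dx", "proc", "med"):
                        w *= p[d] if present[d] else 1 - p[d]
                    total += w
    return (1 - config.p_silent_birth) * total
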