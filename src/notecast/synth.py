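"""Seeded synthetic primary-care EMR cohorts with a plantable cancer signal.

The generator emulates the distributional structure of Dutch GP records
that the downstream analysis assumes, without any linguistic realism:

* a rare binary outcome (colorectal cancer, ICPC ``D75``) at ~0.89%
  prevalence, the D75 code emitted exactly once, at the case's anchor date;
* short noisy notes — 1 to 15 words with the mode at 7 words (~12% of
  notes), drawn from a Zipf(1.05) pseudo-word inventory, with occasional
  typos (adjacent-character swaps), capitalisation and punctuation that the
  cleaning step must strip;
* consultation-level ICPC codes, including the eleven symptom codes the
  tabular model tracks;
* a planted signal: inside a case's observation window (the two years
  ending five months before the D75 date) the emission odds of a designated
  set of signal tokens are multiplied by ``signal_strength``, an adjacent
  signal-token pair is occasionally planted (a learnable bigram), and the
  tracked ICPC codes fire at ``icpc_effect`` times their base rate.

Generated records carry no label field: the outcome is encoded the way a
real EMR encodes it — as a D75-coded consultation — and the labelling logic
in :mod:`notecast.cohort` has to recover it.

Default demographics (prevalence, age mixture by case status, gender
shares, notes per patient) are calibrated to the published composition of a
~60,000-patient Dutch primary-care population; see ``REFERENCE_COUNTS``.
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np

from .cohort import EXCLUSION_DAYS, WINDOW_DAYS, YEAR_DAYS
from .records import CASE_PREFIX, GENDERS, TRACKED_ICPC, Consultation, PatientRecord

__all__ = [
    "SynthConfig",
    "CohortGenerator",
    "ConfigError",
    "generate_cohort",
    "sample_note_length",
    "sample_note_tokens",
    "REFERENCE_COUNTS",
    "reference_percentages",
    "DEFAULT_NOTE_LENGTH_PMF",
    "AGE_BRACKETS",
]


class ConfigError(ValueError):
    """Invalid generator configuration."""


# --- reference population ---------------------------------------------------

#: Group counts of the Dutch primary-care cohort the generator defaults are
#: calibrated to: patients by outcome, female counts, age-bracket counts at
#: the anchor date, and total consultation notes.
REFERENCE_COUNTS = {
    "patients": {"control": 60_100, "case": 541},
    "female": {"control": 33_087, "case": 280},
    "age": {"control": (41_242, 8_342, 4_831, 5_685),
            "case": (127, 135, 139, 140)},
    "notes": {"control": 3_556_133, "case": 41_339},
}

AGE_BRACKETS = ((30, 60), (60, 70), (70, 80), (80, 95))
AGE_BRACKET_LABELS = ("[30-60)", "[60-70)", "[70-80)", "[80-)")


def reference_percentages() -> dict:
    """Recompute the group percentages implied by ``REFERENCE_COUNTS``.

    Returns unrounded values: outcome shares of the total population, female
    share within each outcome group, and age-bracket shares within each
    outcome group.
    """
    n_control = REFERENCE_COUNTS["patients"]["control"]
    n_case = REFERENCE_COUNTS["patients"]["case"]
    total = n_control + n_case
    out = {
        "outcome": {"control": 100 * n_control / total, "case": 100 * n_case / total},
        "female": {
            "control": 100 * REFERENCE_COUNTS["female"]["control"] / n_control,
            "case": 100 * REFERENCE_COUNTS["female"]["case"] / n_case,
        },
        "age": {},
    }
    for group, denom in (("control", n_control), ("case", n_case)):
        out["age"][group] = {
            lab: 100 * cnt / denom
            for lab, cnt in zip(AGE_BRACKET_LABELS, REFERENCE_COUNTS["age"][group])
        }
    return out


DEFAULT_PREVALENCE = round(
    REFERENCE_COUNTS["patients"]["case"]
    / (REFERENCE_COUNTS["patients"]["case"] + REFERENCE_COUNTS["patients"]["control"]),
    4,
)  # 0.0089

#: Probability of each note length 1..15; mode at 7 words with mass 0.12,
#: a flat body and a tail to 15 words.
DEFAULT_NOTE_LENGTH_PMF = (
    0.045, 0.055, 0.065, 0.075, 0.09, 0.11, 0.12, 0.105,
    0.09, 0.07, 0.055, 0.045, 0.035, 0.025, 0.015,
)


def _default_age_mixture() -> dict:
    return {
        "control": tuple(
            c / REFERENCE_COUNTS["patients"]["control"]
            for c in REFERENCE_COUNTS["age"]["control"]
        ),
        "case": tuple(
            c / REFERENCE_COUNTS["patients"]["case"]
            for c in REFERENCE_COUNTS["age"]["case"]
        ),
    }


def _default_female_fraction() -> dict:
    return {
        "control": REFERENCE_COUNTS["female"]["control"] / REFERENCE_COUNTS["patients"]["control"],
        "case": REFERENCE_COUNTS["female"]["case"] / REFERENCE_COUNTS["patients"]["case"],
    }


# --- configuration ----------------------------------------------------------

@dataclass
class SynthConfig:
    """All knobs of the synthetic cohort process.

    The defaults are the study conditions: 0.89% prevalence, ~59 notes per
    control (76 per case) over the whole record, note lengths 1..15 with
    mode 7, and moderate planted text/code effects in case windows.
    """

    seed: int = 0
    n_patients: int = 10_000
    prevalence: float = DEFAULT_PREVALENCE
    vocab_size: int = 2_000
    n_signal_tokens: int = 20
    signal_strength: float = 10.0      # odds multiplier for signal tokens in case windows
    icpc_effect: float = 3.0           # rate multiplier for tracked ICPC codes in case windows
    note_length_pmf: tuple = DEFAULT_NOTE_LENGTH_PMF
    consults_per_patient_mean: float = 59.0
    case_consults_mean: float = 76.0
    consult_dispersion: float = 0.75   # gamma-Poisson shape; sd ~ mean as observed
    date_range: tuple = (dt.date(1995, 1, 1), dt.date(2015, 1, 1))
    age_mixture: dict = field(default_factory=_default_age_mixture)
    female_fraction: dict = field(default_factory=_default_female_fraction)
    other_gender_fraction: float = 0.005
    under_age_fraction: float = 0.05   # controls below the age gate (embedding corpus only)
    empty_note_fraction: float = 0.08
    codes_per_consult_mean: float = 0.7
    typo_rate: float = 0.02
    #: base rate of the designated adjacent signal pair per (eligible) note;
    #: inside a case window the rate is multiplied by signal_strength, so a
    #: null configuration (signal_strength = 1) plants nothing
    background_bigram_rate: float = 0.02
    zipf_exponent: float = 1.05

    def validate(self) -> None:
        if not (0.0 <= self.prevalence < 1.0):
            raise ConfigError(f"prevalence must be in [0, 1), got {self.prevalence}")
        pmf = np.asarray(self.note_length_pmf, dtype=float)
        if pmf.ndim != 1 or pmf.size < 1 or np.any(pmf < 0):
            raise ConfigError("note_length_pmf must be a non-negative vector")
        if abs(pmf.sum() - 1.0) > 1e-9:
            raise ConfigError(f"note_length_pmf sums to {pmf.sum()!r}, expected 1")
        if pmf.size >= 7 and int(np.argmax(pmf)) != 6:
            raise ConfigError("note_length_pmf must have its mode at length 7")
        if self.signal_strength < 1.0:
            raise ConfigError("signal_strength must be >= 1")
        if self.icpc_effect < 1.0:
            raise ConfigError("icpc_effect must be >= 1")
        for name in ("vocab_size", "n_signal_tokens"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.n_signal_tokens > self.vocab_size:
            raise ConfigError("n_signal_tokens cannot exceed vocab_size")
        if self.date_range[0] >= self.date_range[1]:
            raise ConfigError("empty date_range")


# --- token inventory --------------------------------------------------------

_SYLLABLES = [c + v for c in "bdfghklmnprstvwz" for v in "aeiou"]  # 80 syllables


def token_word(i: int) -> str:
    """Deterministic unique pseudo-word for vocabulary index i."""
    return _SYLLABLES[(i // 80) % 80] + _SYLLABLES[i % 80]


def _swap_typo(word: str, rng: np.random.Generator) -> str:
    if len(word) < 2:
        return word
    j = int(rng.integers(0, len(word) - 1))
    return word[:j] + word[j + 1] + word[j] + word[j + 2:]


def _draw_cdf(cdf: np.ndarray, size: int, rng: np.random.Generator) -> np.ndarray:
    return np.searchsorted(cdf, rng.random(size), side="right")


# --- generator --------------------------------------------------------------

class CohortGenerator:
    """Generates a cohort from a :class:`SynthConfig`; deterministic per seed.

    After :meth:`generate`, ``case_ids`` holds the planted case set — the
    ground truth the labelling stage must recover.
    """

    def __init__(self, config: SynthConfig):
        config.validate()
        self.cfg = config
        self.case_ids: set[str] = set()
        self._init_tokens()
        self._init_codes()
        pmf = np.asarray(config.note_length_pmf, dtype=float)
        self._length_cdf = np.cumsum(pmf / pmf.sum())

    # -- token model
    def _init_tokens(self) -> None:
        cfg = self.cfg
        n = max(cfg.vocab_size, 1)
        ranks = np.arange(1, n + 1, dtype=float)
        p = ranks ** -cfg.zipf_exponent
        p /= p.sum()
        self.tokens = [token_word(i) for i in range(n)]
        # Signal tokens sit at mid-frequency ranks: common enough to clear
        # the min-count filter, rare enough to escape heavy subsampling.
        step = max(1, (n - 100) // max(cfg.n_signal_tokens, 1))
        idx = 100 + np.arange(cfg.n_signal_tokens) * min(step, 20)
        self.signal_indices = np.unique(np.clip(idx, 0, n - 1))
        self.signal_tokens = [self.tokens[i] for i in self.signal_indices]
        self.signal_mass_base = float(p[self.signal_indices].sum()) if len(self.signal_indices) else 0.0
        p_case = p.copy()
        m = self.signal_mass_base
        if 0.0 < m < 1.0:
            odds = m / (1.0 - m) * cfg.signal_strength
            m_case = odds / (1.0 + odds)
            scale_sig = m_case / m
            scale_bg = (1.0 - m_case) / (1.0 - m)
            p_case *= scale_bg
            p_case[self.signal_indices] = p[self.signal_indices] * scale_sig
            self.signal_mass_case = m_case
        else:
            self.signal_mass_case = m
        self._base_cdf = np.cumsum(p)
        self._case_cdf = np.cumsum(p_case / p_case.sum())
        self.bigram_pair = tuple(self.signal_tokens[:2]) if len(self.signal_tokens) >= 2 else None

    # -- code model
    def _init_codes(self) -> None:
        cfg = self.cfg
        background = []
        for letter in "ALKRSDPBTUN":
            for num in range(1, 31):
                code = f"{letter}{num:02d}"
                if code in TRACKED_ICPC or code.startswith(CASE_PREFIX):
                    continue
                background.append(code)
                if len(background) >= 70:
                    break
            if len(background) >= 70:
                break
        self.codes = list(TRACKED_ICPC) + background
        tracked_mass = 0.12
        w = np.empty(len(self.codes))
        w[: len(TRACKED_ICPC)] = tracked_mass / len(TRACKED_ICPC)
        bg = np.arange(1, len(background) + 1, dtype=float) ** -1.0
        w[len(TRACKED_ICPC):] = (1.0 - tracked_mass) * bg / bg.sum()
        self._code_base_cdf = np.cumsum(w / w.sum())
        w_case = w.copy()
        w_case[: len(TRACKED_ICPC)] *= cfg.icpc_effect
        self._code_case_cdf = np.cumsum(w_case / w_case.sum())

    # -- sampling primitives
    def sample_note_length(self, rng: np.random.Generator) -> int:
        """One draw from the note-length distribution (support 1..len(pmf))."""
        return int(_draw_cdf(self._length_cdf, 1, rng)[0]) + 1

    def sample_note_tokens(
        self, length: int, in_case_window: bool, rng: np.random.Generator
    ) -> list[str]:
        """Sample the tokens of one note.

        In a case window each emission is a signal token with odds boosted
        by ``signal_strength``; occasionally an adjacent signal pair (the
        plantable bigram) is inserted, and tokens receive typo variants.
        """
        cfg = self.cfg
        cdf = self._case_cdf if in_case_window else self._base_cdf
        idx = _draw_cdf(cdf, length, rng)
        toks = [self.tokens[i] for i in idx]
        pair_rate = cfg.background_bigram_rate * (cfg.signal_strength if in_case_window else 1.0)
        pair_rate = min(pair_rate, 1.0)
        if self.bigram_pair is not None and length >= 2 and rng.random() < pair_rate:
            j = int(rng.integers(0, length - 1))
            toks[j], toks[j + 1] = self.bigram_pair
        if cfg.typo_rate > 0.0:
            mask = rng.random(length) < cfg.typo_rate
            for j in np.nonzero(mask)[0]:
                toks[j] = _swap_typo(toks[j], rng)
        return toks

    def _sample_codes(self, k: int, in_case_window: bool, rng: np.random.Generator) -> list[str]:
        if k <= 0:
            return []
        cdf = self._code_case_cdf if in_case_window else self._code_base_cdf
        return [self.codes[i] for i in _draw_cdf(cdf, k, rng)]

    def _note_text(self, in_case_window: bool, rng: np.random.Generator) -> str:
        cfg = self.cfg
        if rng.random() < cfg.empty_note_fraction:
            return ""
        toks = self.sample_note_tokens(self.sample_note_length(rng), in_case_window, rng)
        s = " ".join(toks)
        if rng.random() < 0.25:
            s = s[0].upper() + s[1:]
        if rng.random() < 0.2:
            s += (".", "..", "?", ",", "!")[int(rng.integers(0, 5))]
        return s

    def _consult_count(self, mean: float, rng: np.random.Generator) -> int:
        lam = rng.gamma(self.cfg.consult_dispersion, mean / self.cfg.consult_dispersion)
        return int(rng.poisson(lam))

    # -- per-patient process
    def _patient(self, pid: str, is_case: bool, rng: np.random.Generator) -> PatientRecord:
        cfg = self.cfg
        start_ord = cfg.date_range[0].toordinal()
        end_ord = cfg.date_range[1].toordinal()
        span = int(rng.integers(3 * YEAR_DAYS, min(15 * YEAR_DAYS, end_ord - start_ord)))
        rec_start = int(rng.integers(start_ord, end_ord - span))
        rec_end = rec_start + span

        if is_case:
            anchor = int(rng.integers(rec_start + WINDOW_DAYS + EXCLUSION_DAYS, rec_end + 1))
            # the record is censored at diagnosis: the target count refers to
            # the full span, so scale by the observed fraction to keep the
            # consultation *density* comparable with controls
            n_full = self._consult_count(cfg.case_consults_mean, rng)
            n_cons = max(3, int(round(n_full * (anchor - rec_start) / span)))
            dates = rng.integers(rec_start, anchor, n_cons)
            win_lo, win_hi = anchor - EXCLUSION_DAYS - WINDOW_DAYS, anchor - EXCLUSION_DAYS
            n_in_win = int(np.count_nonzero((dates >= win_lo) & (dates < win_hi)))
            if n_in_win < 2:  # cases present to their GP inside the window
                extra = rng.integers(win_lo, win_hi, 2 - n_in_win)
                dates = np.concatenate([dates, extra])
        else:
            anchor = None
            n_cons = max(1, self._consult_count(cfg.consults_per_patient_mean, rng))
            dates = rng.integers(rec_start, rec_end + 1, n_cons)
        dates = np.sort(dates)
        if anchor is None:
            anchor = int(dates[-1])

        # age at anchor, in whole days, drawn from the bracket mixture
        if is_case:
            mix = cfg.age_mixture["case"]
            bracket = AGE_BRACKETS[_draw_cdf(np.cumsum(mix), 1, rng)[0]]
            age_days = int(rng.integers(bracket[0] * YEAR_DAYS + 1, bracket[1] * YEAR_DAYS))
        elif rng.random() < cfg.under_age_fraction:
            age_days = int(rng.integers(18 * YEAR_DAYS, 30 * YEAR_DAYS))
        else:
            mix = cfg.age_mixture["control"]
            bracket = AGE_BRACKETS[_draw_cdf(np.cumsum(mix), 1, rng)[0]]
            age_days = int(rng.integers(bracket[0] * YEAR_DAYS + 1, bracket[1] * YEAR_DAYS))
        birth = dt.date.fromordinal(anchor - age_days)

        group = "case" if is_case else "control"
        p_female = cfg.female_fraction[group]
        u = rng.random()
        if u < p_female:
            gender = "female"
        elif u < p_female + cfg.other_gender_fraction:
            gender = "other"
        else:
            gender = "male"

        win_lo = anchor - EXCLUSION_DAYS - WINDOW_DAYS
        win_hi = anchor - EXCLUSION_DAYS
        consultations: list[Consultation] = []
        for d in dates:
            boosted = bool(is_case and win_lo <= d < win_hi)
            k_codes = int(rng.poisson(cfg.codes_per_consult_mean))
            consultations.append(
                Consultation(
                    date=dt.date.fromordinal(int(d)),
                    icpc_codes=self._sample_codes(k_codes, boosted, rng),
                    note_text=self._note_text(boosted, rng),
                )
            )
        if is_case:
            # the diagnosis itself: D75 exactly once, at the anchor date
            consultations.append(
                Consultation(
                    date=dt.date.fromordinal(anchor),
                    icpc_codes=[CASE_PREFIX],
                    note_text=self._note_text(False, rng),
                )
            )
        return PatientRecord(pid, birth, gender, consultations)

    def generate(self) -> list[PatientRecord]:
        cfg = self.cfg
        rng = np.random.default_rng(cfg.seed)
        self.case_ids = set()
        if cfg.n_patients <= 0:
            return []
        is_case = rng.random(cfg.n_patients) < cfg.prevalence
        records = []
        for i in range(cfg.n_patients):
            pid = f"p{i:06d}"
            if is_case[i]:
                self.case_ids.add(pid)
            records.append(self._patient(pid, bool(is_case[i]), rng))
        return records


# --- module-level operations ------------------------------------------------

def generate_cohort(config: SynthConfig) -> list[PatientRecord]:
    """Generate a cohort; deterministic given ``config.seed``."""
    return CohortGenerator(config).generate()


def sample_note_length(rng: np.random.Generator, note_length_pmf=None) -> int:
    """Draw one note length from the given pmf (default: the study pmf)."""
    pmf = np.asarray(
        DEFAULT_NOTE_LENGTH_PMF if note_length_pmf is None else note_length_pmf, dtype=float
    )
    if np.any(pmf < 0) or abs(pmf.sum() - 1.0) > 1e-9:
        raise ConfigError("invalid note-length pmf")
    return int(np.searchsorted(np.cumsum(pmf), rng.random(), side="right")) + 1


def sample_note_tokens(
    length: int,
    in_case_window: bool,
    rng: np.random.Generator,
    config: SynthConfig | None = None,
) -> list[str]:
    """Sample one note's tokens under the given (or default) configuration.

    Convenience wrapper; for bulk sampling build one
    :class:`CohortGenerator` and call its method directly.
    """
    gen = CohortGenerator(config if config is not None else SynthConfig())
    return gen.sample_note_tokens(length, in_case_window, rng)
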