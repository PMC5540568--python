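"""EU-guideline performance indicators and screened-vs-unscreened reductions.

Indicator conventions (verified to reproduce the Basque programme's
published 2009-2014 results table):

* participation = participants / invited (%)
* positivity = positive tests / participants (%)
* colonoscopy adherence = diagnostic colonoscopies / positive tests (%)
* PPV for advanced adenoma (AA), advanced neoplasia (AN) and CRC uses
  **positive tests** as the denominator (not colonoscopies performed) -
  both conventions exist in the literature; this one matches the
  published table (e.g. women total CRC 725/16,325 = 4.4%).
* detection rates are per 1000 participants (per mille)
* the stage distribution is over detected CRC.

Zero denominators yield missing values (NaN), never exceptions.
Rounding is half-up to one decimal and happens only in the display
layer; internal values keep full precision.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ConfigurationError

COUNT_COLUMNS = ("eligible", "invited", "participants", "positives",
                 "colonoscopies", "detected_advanced_adenoma",
                 "detected_advanced_neoplasia", "detected_crc",
                 "crc_stage_i_ii", "crc_stage_iii_iv", "crc_stage_unknown")

INDICATOR_COLUMNS = ("participation_pct", "positivity_pct",
                     "colonoscopy_adherence_pct",
                     "ppv_advanced_adenoma_pct", "ppv_advanced_neoplasia_pct",
                     "ppv_crc_pct",
                     "detection_advanced_adenoma_permille",
                     "detection_advanced_neoplasia_permille",
                     "detection_crc_permille",
                     "stage_i_ii_pct", "stage_iii_iv_pct",
                     "stage_unknown_pct")


def round_half_up(x, decimals: int = 1):
    """Round non-negative values half-up (2.65 -> 2.7), NaN-safe."""
    x = np.asarray(x, dtype=float)
    scale = 10.0 ** decimals
    out = np.floor(x * scale + 0.5) / scale
    return np.where(np.isnan(x), np.nan, out)


@dataclass
class CountTable:
    """Aggregated programme counts keyed by (sex, round).

    Wraps a DataFrame with index (sex, round) and the columns in
    :data:`COUNT_COLUMNS`.  The invariant chain invited <= eligible,
    participants <= invited, positives <= participants, colonoscopies <=
    positives and stage sums = detected CRC is validated on creation.
    """

    data: pd.DataFrame

    def __post_init__(self):
        df = self.data
        if not isinstance(df.index, pd.MultiIndex):
            df = df.set_index(["sex", "round"])
            self.data = df
        missing = set(COUNT_COLUMNS) - set(df.columns)
        if missing:
            raise ConfigurationError(f"count table misses columns {sorted(missing)}")
        self.validate()

    @classmethod
    def from_csv(cls, path) -> "CountTable":
        return cls(pd.read_csv(path))

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False)

    def validate(self) -> None:
        df = self.data
        chain = ["eligible", "invited", "participants", "positives",
                 "colonoscopies"]
        for hi, lo in zip(chain, chain[1:]):
            if np.any(df[lo] > df[hi]):
                raise ConfigurationError(f"{lo} exceeds {hi} in some row")
        stage_sum = (df["crc_stage_i_ii"] + df["crc_stage_iii_iv"]
                     + df["crc_stage_unknown"])
        if np.any(stage_sum != df["detected_crc"]):
            raise ConfigurationError("stage groups do not sum to detected CRC")
        if np.any(df[list(COUNT_COLUMNS)] < 0):
            raise ConfigurationError("counts must be >= 0")

    def with_totals(self) -> pd.DataFrame:
        """Rows plus per-sex totals and the grand total row."""
        df = self.data.copy()
        pieces = [df]
        for sex, g in df.groupby(level="sex", sort=True):
            tot = g.sum()
            tot.name = (sex, "total")
            pieces.append(tot.to_frame().T)
        grand = df.sum()
        grand.name = ("all", "total")
        pieces.append(grand.to_frame().T)
        out = pd.concat(pieces)
        out.index = pd.MultiIndex.from_tuples(out.index, names=["sex", "round"])
        return out


@dataclass
class IndicatorTable:
    """Performance indicators per (sex, round), with totals rows."""

    data: pd.DataFrame

    def rounded(self, decimals: int = 1) -> pd.DataFrame:
        return self.data.apply(lambda c: round_half_up(c, decimals))

    def to_csv(self, path) -> None:
        self.data.reset_index().to_csv(path, index=False)

    def report(self) -> str:
        """Human-readable fixed-precision report."""
        lines = ["Programme performance indicators", "=" * 34]
        r = self.rounded()
        for (sex, rnd), row in r.iterrows():
            lines.append(f"\n[{sex} / round {rnd}]")
            for col in INDICATOR_COLUMNS:
                v = row[col]
                txt = "missing" if np.isnan(v) else f"{v:.1f}"
                lines.append(f"  {col:38s} {txt}")
        return "\n".join(lines) + "\n"


def _ratio(num, den, scale):
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = scale * num / den
    return np.where(den > 0, out, np.nan)


def compute_indicators(counts: CountTable) -> IndicatorTable:
    """Derive the indicator table from aggregated counts.

    Operates on every (sex, round) row plus per-sex totals and the grand
    total.  Zero denominators are flagged as missing (NaN).
    """
    df = counts.with_totals()
    out = pd.DataFrame(index=df.index)
    out["participation_pct"] = _ratio(df["participants"], df["invited"], 100)
    out["positivity_pct"] = _ratio(df["positives"], df["participants"], 100)
    out["colonoscopy_adherence_pct"] = _ratio(df["colonoscopies"],
                                              df["positives"], 100)
    for lesion in ("advanced_adenoma", "advanced_neoplasia", "crc"):
        col = f"detected_{lesion}"
        out[f"ppv_{lesion}_pct"] = _ratio(df[col], df["positives"], 100)
        out[f"detection_{lesion}_permille"] = _ratio(df[col],
                                                     df["participants"], 1000)
    for grp in ("i_ii", "iii_iv", "unknown"):
        out[f"stage_{grp}_pct"] = _ratio(df[f"crc_stage_{grp}"],
                                         df["detected_crc"], 100)
    return IndicatorTable(out)


# ---------------------------------------------------------------------------
# Reductions and life-years lost


@dataclass
class ReductionSummary:
    """Percentage reductions of the screening arm vs no screening.

    ``annual_*`` compares single-year counts; ``cumulative_*`` compares
    counts accumulated from the first projection year.  A reduction is
    100 x (no-screening - screening) / no-screening and is NaN where the
    no-screening denominator is zero.  ``at_horizon`` holds the
    cumulative values in the final projection year.
    """

    sex: str
    years: np.ndarray
    annual_incidence: np.ndarray
    annual_mortality: np.ndarray
    annual_lyl: np.ndarray
    cumulative_incidence: np.ndarray
    cumulative_mortality: np.ndarray
    cumulative_lyl: np.ndarray

    @property
    def at_horizon(self) -> dict:
        return {"incidence": float(self.cumulative_incidence[-1]),
                "mortality": float(self.cumulative_mortality[-1]),
                "lyl": float(self.cumulative_lyl[-1])}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "year": self.years.astype(int),
            "annual_incidence_reduction_pct": self.annual_incidence,
            "annual_mortality_reduction_pct": self.annual_mortality,
            "annual_lyl_reduction_pct": self.annual_lyl,
            "cumulative_incidence_reduction_pct": self.cumulative_incidence,
            "cumulative_mortality_reduction_pct": self.cumulative_mortality,
            "cumulative_lyl_reduction_pct": self.cumulative_lyl,
        }).assign(sex=self.sex)


def _reduction(no_screen: np.ndarray, screen: np.ndarray) -> np.ndarray:
    no_screen = np.asarray(no_screen, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = 100.0 * (no_screen - np.asarray(screen, dtype=float)) / no_screen
    return np.where(no_screen > 0, r, np.nan)


def reduction_series(no_screening, screening) -> ReductionSummary:
    """Annual and cumulative reduction trajectories for a scenario pair.

    Both results must share the calendar index; incidence uses all CRC
    diagnoses (any mode), mortality uses CRC deaths, LYL uses the
    life-years-lost attached to the CRC death year.
    """
    if not np.array_equal(no_screening.years, screening.years):
        raise ConfigurationError("scenario calendars do not match")
    pairs = {}
    for name, attr in (("incidence", "crc_incidence"),
                       ("mortality", "crc_deaths"),
                       ("lyl", "life_years_lost")):
        u = getattr(no_screening, attr)
        s = getattr(screening, attr)
        pairs[name] = (_reduction(u, s),
                       _reduction(np.cumsum(u), np.cumsum(s)))
    return ReductionSummary(
        sex=screening.sex, years=no_screening.years.copy(),
        annual_incidence=pairs["incidence"][0],
        annual_mortality=pairs["mortality"][0],
        annual_lyl=pairs["lyl"][0],
        cumulative_incidence=pairs["incidence"][1],
        cumulative_mortality=pairs["mortality"][1],
        cumulative_lyl=pairs["lyl"][1])


def life_years_lost(crc_death_ages, other_cause_death_ages, *,
                    birth_years=None, baseline_year=None,
                    horizon=None) -> float:
    """Total life-years lost to CRC.

    LYL is the sum of max(0, other-cause death age - CRC death age) over
    persons dying of CRC; when ``baseline_year``/``horizon`` are given,
    only CRC deaths inside the projection window are counted.
    """
    crc = np.asarray(crc_death_ages, dtype=float)
    oc = np.asarray(other_cause_death_ages, dtype=float)
    died = np.isfinite(crc) & (crc < oc)
    if horizon is not None and baseline_year is not None:
        if birth_years is None:
            raise ConfigurationError("birth years needed for a horizon window")
        t = np.asarray(birth_years, dtype=float) + crc
        died &= (t >= baseline_year + 1) & (t < baseline_year + 1 + horizon)
    return float(np.sum(np.maximum(0.0, oc[died] - crc[died])))
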