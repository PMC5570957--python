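"""Plate-scale screening: scheduling, aggregation, hit calling, time courses.

Implements the statistical layer of a compound screen on aged worms:

* a processing plan that interleaves vehicle-control wells after every block
  of compound wells (default 9), so each compound is compared to untreated
  worms of exactly the same age;
* per-well aggregation with QC discard accounting (SEM error bars);
* percent-effect hit calling: the effect of a compound is the percent
  difference of the treated group's mean peak from its matched control's,
  with a two-sided unequal-variance (Welch) test on per-worm peaks;
* aging trajectories (one-way ANOVA + pairwise tests), treated-vs-control
  time courses (two-way ANOVA + per-day Bonferroni), and dose-response
  analysis (one-way ANOVA + pairwise vs vehicle).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from statsmodels.formula.api import ols
from statsmodels.stats.anova import anova_lm
from statsmodels.stats.multitest import multipletests

__all__ = [
    "PlateLayout",
    "phase_bin",
    "PlanItem",
    "schedule",
    "WellSummary",
    "summarize_well",
    "welch_test",
    "CompoundEffect",
    "compound_effect",
    "HitSummary",
    "call_hits",
    "aging_trajectory",
    "two_group_timecourse",
    "dose_response",
]

ROWS = "ABCDEFGH"
N_COLS = 12


def phase_bin(day: int) -> str:
    """Adulthood phase: early (<= Day 6), mid (Day 7-8), late (>= Day 9)."""
    if day >= 9:
        return "late"
    if day >= 7:
        return "mid"
    return "early"


class PlateLayout:
    """An 8x12 well grid with per-well roles.

    Roles are ``compound`` (carries a compound id and a concentration),
    ``vehicle_control`` (solvent only, 0.4% DMSO) or ``medium_only``.  The
    default library plate puts vehicle controls in column 11 and assay
    medium in the edge wells (columns 1 & 12, rows A & H) to avoid edge
    effects; compounds occupy rows B-G of columns 2-10 at 20 uM.
    """

    def __init__(
        self,
        roles: dict[str, str],
        compounds: dict[str, str] | None = None,
        concentrations: dict[str, float] | None = None,
        vehicle: str = "0.4% DMSO",
    ) -> None:
        for well, role in roles.items():
            self._check_well(well)
            if role not in ("compound", "vehicle_control", "medium_only"):
                raise ValueError(f"unknown role {role!r} at {well}")
        self.roles = dict(roles)
        self.compounds = dict(compounds or {})
        self.concentrations = dict(concentrations or {})
        self.vehicle = vehicle
        for well in self.compound_wells():
            if well not in self.compounds:
                raise ValueError(f"compound well {well} has no compound id")
            self.concentrations.setdefault(well, 20.0)

    @staticmethod
    def _check_well(well: str) -> None:
        if len(well) < 2 or well[0] not in ROWS or not well[1:].isdigit():
            raise ValueError(f"malformed well id {well!r}")
        if not 1 <= int(well[1:]) <= N_COLS:
            raise ValueError(f"column out of range in {well!r}")

    @classmethod
    def default_library(
        cls, compounds: list[str], concentration_uM: float = 20.0
    ) -> "PlateLayout":
        roles: dict[str, str] = {}
        comp_map: dict[str, str] = {}
        conc: dict[str, float] = {}
        free = []
        for row in ROWS:
            for col in range(1, N_COLS + 1):
                well = f"{row}{col}"
                if row in "AH" or col in (1, 12):
                    roles[well] = "medium_only"
                elif col == 11:
                    roles[well] = "vehicle_control"
                else:
                    free.append(well)
        if len(compounds) > len(free):
            raise ValueError(
                f"{len(compounds)} compounds do not fit the {len(free)} compound wells"
            )
        for well, name in zip(free, compounds):
            roles[well] = "compound"
            comp_map[well] = name
            conc[well] = concentration_uM
        for well in free[len(compounds):]:
            roles[well] = "medium_only"
        return cls(roles, comp_map, conc)

    @classmethod
    def library_series(
        cls, compounds: list[str], concentration_uM: float = 20.0
    ) -> list["PlateLayout"]:
        """As many default library plates as needed to hold all compounds."""
        per_plate = 54  # rows B-G x columns 2-10
        return [
            cls.default_library(compounds[i : i + per_plate], concentration_uM)
            for i in range(0, len(compounds), per_plate)
        ]

    def wells(self) -> list[str]:
        return sorted(self.roles, key=lambda w: (w[0], int(w[1:])))

    def role(self, well: str) -> str:
        return self.roles[well]

    def compound(self, well: str) -> str:
        return self.compounds.get(well, "")

    def concentration(self, well: str) -> float:
        return self.concentrations.get(well, 0.0)

    def compound_wells(self) -> list[str]:
        return [w for w in self.wells() if self.roles[w] == "compound"]

    def control_wells(self) -> list[str]:
        return [w for w in self.wells() if self.roles[w] == "vehicle_control"]

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {
                    "vehicle": self.vehicle,
                    "roles": self.roles,
                    "compounds": self.compounds,
                    "concentrations_uM": self.concentrations,
                },
                fh,
                sort_keys=True,
            )

    @classmethod
    def from_yaml(cls, path) -> "PlateLayout":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        return cls(
            d["roles"],
            d.get("compounds"),
            d.get("concentrations_uM"),
            d.get("vehicle", "0.4% DMSO"),
        )


@dataclass(frozen=True)
class PlanItem:
    kind: str          # "well" | "wash"
    well: str = ""
    role: str = ""
    plate: int = 0


def schedule(
    layouts: "PlateLayout | list[PlateLayout]",
    controls_every: int = 9,
    wash_every_n_worms: int | None = None,
    worms_per_well: int = 15,
) -> list[PlanItem]:
    """Ordered processing plan with interleaved controls and wash events.

    Every compound well is visited exactly once; after each block of
    ``controls_every`` compound wells (including a trailing partial block)
    the next vehicle-control well is inserted, cycling through the
    available controls.  Medium-only wells are never scheduled.  When
    ``wash_every_n_worms`` is set, a wash event is inserted each time that
    many worms have been processed since the last wash.
    """
    if controls_every < 1:
        raise ValueError("controls_every must be >= 1")
    plates = layouts if isinstance(layouts, list) else [layouts]
    compounds = [(i, w) for i, p in enumerate(plates) for w in p.compound_wells()]
    vehicles = [(i, w) for i, p in enumerate(plates) for w in p.control_wells()]
    if not vehicles:
        raise ValueError("layout must contain at least one vehicle-control well")

    plan: list[PlanItem] = []
    vi = 0
    block = 0
    for plate_i, well in compounds:
        plan.append(PlanItem("well", well, "compound", plate_i))
        block += 1
        if block == controls_every:
            pv, wv = vehicles[vi % len(vehicles)]
            plan.append(PlanItem("well", wv, "vehicle_control", pv))
            vi += 1
            block = 0
    if block > 0:
        pv, wv = vehicles[vi % len(vehicles)]
        plan.append(PlanItem("well", wv, "vehicle_control", pv))

    if wash_every_n_worms is not None:
        if wash_every_n_worms < 1:
            raise ValueError("wash_every_n_worms must be >= 1")
        with_wash: list[PlanItem] = []
        acc = 0
        for item in plan:
            with_wash.append(item)
            acc += worms_per_well
            while acc >= wash_every_n_worms:
                with_wash.append(PlanItem("wash"))
                acc -= wash_every_n_worms
        plan = with_wash
    return plan


@dataclass
class WellSummary:
    well: str
    n_analyzed: int
    n_discarded: dict[str, int]
    mean_peak: float
    sem_peak: float
    mean_slope: float
    sem_slope: float
    empty: bool = False


def _analyzed(records: pd.DataFrame) -> pd.DataFrame:
    if "qc" in records.columns:
        return records[records["qc"] == "analyzed"]
    return records


def summarize_well(records: pd.DataFrame, well: str | None = None) -> WellSummary:
    """Mean and SEM of peak and slope over the analyzed worms of one well."""
    if len(records) == 0:
        raise ValueError("summarize_well needs at least one record")
    well = well or (records["well"].iloc[0] if "well" in records.columns else "")
    ok = _analyzed(records)
    discards = (
        records.loc[records["qc"] != "analyzed", "qc"].value_counts().to_dict()
        if "qc" in records.columns
        else {}
    )
    n = len(ok)
    if n == 0:
        return WellSummary(well, 0, discards, np.nan, np.nan, np.nan, np.nan, empty=True)

    def sem(x: np.ndarray) -> float:
        return float(np.std(x, ddof=1) / math.sqrt(len(x))) if len(x) >= 2 else np.nan

    peaks = ok["peak_pct"].to_numpy(float)
    slopes = ok["slope_pct_s"].to_numpy(float)
    return WellSummary(
        well, n, discards,
        float(peaks.mean()), sem(peaks), float(slopes.mean()), sem(slopes),
    )


def welch_test(a: np.ndarray, b: np.ndarray) -> tuple[float, float, float]:
    """Two-sided unequal-variance two-sample location test.

    Returns ``(t, df, p)``; identical to ``scipy.stats.ttest_ind(a, b,
    equal_var=False)`` but computed from group summaries for speed.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = a.size, b.size
    if na < 2 or nb < 2:
        raise ValueError("both groups need n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    se2 = va / na + vb / nb
    if se2 == 0:
        return 0.0, float(na + nb - 2), 1.0
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2 * se2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * float(stats.t.sf(abs(t), df))
    return float(t), float(df), p


@dataclass
class CompoundEffect:
    """Percent effect of one compound on the transient peak, vs matched control."""

    compound: str
    effect_pct: float
    effect_slope_pct: float
    p_value: float
    p_slope: float
    classification: str        # positive | negative | none
    dual_action: bool
    n_treated: int
    n_control: int
    p_adj: float | None = None

    @staticmethod
    def classify(effect_pct: float, p: float, alpha: float) -> str:
        if p >= alpha or effect_pct == 0:
            return "none"
        return "positive" if effect_pct > 0 else "negative"


def _extract(records, column: str) -> np.ndarray:
    if isinstance(records, pd.DataFrame):
        return _analyzed(records)[column].to_numpy(float)
    return np.asarray(records, dtype=float)


def compound_effect(
    treated,
    control,
    alpha: float = 0.05,
    compound: str = "",
) -> CompoundEffect:
    """Table-1-style statistic: percent difference of group mean peaks + Welch p.

    ``treated``/``control`` are per-worm record frames (only ``analyzed``
    rows contribute) or plain arrays of peak values.  Ages must match when
    both frames carry an ``age_day`` column — the comparison is only
    meaningful between worms of the same age.
    """
    if isinstance(treated, pd.DataFrame) and isinstance(control, pd.DataFrame):
        if "age_day" in treated.columns and "age_day" in control.columns:
            at, ac = set(treated["age_day"]), set(control["age_day"])
            if at and ac and at != ac:
                raise ValueError(f"treated ages {at} do not match control ages {ac}")
        if not compound and "compound" in treated.columns and len(treated):
            compound = str(treated["compound"].iloc[0])
    tp, cp = _extract(treated, "peak_pct"), _extract(control, "peak_pct")
    if tp.size < 2 or cp.size < 2:
        raise ValueError("both groups need at least 2 analyzed worms")
    mc = cp.mean()
    if mc <= 0:
        raise ValueError(f"non-positive control mean peak {mc}")
    effect = 100.0 * (tp.mean() - mc) / mc
    _, _, p = welch_test(tp, cp)

    effect_slope, p_slope = np.nan, np.nan
    try:
        ts, cs = _extract(treated, "slope_pct_s"), _extract(control, "slope_pct_s")
        if ts.size >= 2 and cs.size >= 2 and cs.mean() > 0:
            effect_slope = 100.0 * (ts.mean() - cs.mean()) / cs.mean()
            _, _, p_slope = welch_test(ts, cs)
    except (KeyError, IndexError, TypeError):
        pass

    cls = CompoundEffect.classify(effect, p, alpha)
    dual = bool(
        cls == "positive"
        and np.isfinite(p_slope)
        and p_slope < alpha
        and effect_slope > 0
    )
    return CompoundEffect(
        compound=compound,
        effect_pct=float(effect),
        effect_slope_pct=float(effect_slope),
        p_value=float(p),
        p_slope=float(p_slope),
        classification=cls,
        dual_action=dual,
        n_treated=int(tp.size),
        n_control=int(cp.size),
    )


@dataclass
class HitSummary:
    """Partition of a screen's compounds by effect direction."""

    positives: list[CompoundEffect]
    negatives: list[CompoundEffect]
    no_effect: list[CompoundEffect]
    alpha: float
    multiple_testing: str

    @property
    def counts(self) -> dict[str, int]:
        return {
            "positive": len(self.positives),
            "negative": len(self.negatives),
            "none": len(self.no_effect),
        }

    @property
    def fractions(self) -> dict[str, float]:
        total = sum(self.counts.values())
        return {k: v / total for k, v in self.counts.items()}


def call_hits(
    effects: list[CompoundEffect],
    alpha: float = 0.05,
    multiple_testing: str = "none",
) -> HitSummary:
    """Partition compounds into positive / negative / no effect.

    ``multiple_testing='bh'`` recomputes the classification on
    Benjamini-Hochberg adjusted p-values (the raw per-compound p-values are
    kept alongside).
    """
    if not effects:
        raise ValueError("no compound effects to classify")
    if multiple_testing not in ("none", "bh"):
        raise ValueError(f"unknown multiple-testing mode {multiple_testing!r}")
    if multiple_testing == "bh":
        p_adj = multipletests([e.p_value for e in effects], method="fdr_bh")[1]
        for e, pa in zip(effects, p_adj):
            e.p_adj = float(pa)
            e.classification = CompoundEffect.classify(e.effect_pct, pa, alpha)
    groups: dict[str, list[CompoundEffect]] = {"positive": [], "negative": [], "none": []}
    for e in effects:
        groups[e.classification].append(e)
    return HitSummary(groups["positive"], groups["negative"], groups["none"], alpha, multiple_testing)


@dataclass
class AgingResult:
    per_day: pd.DataFrame
    anova_p_peak: float
    anova_p_slope: float
    pairwise: pd.DataFrame
    excluded_days: list[int] = field(default_factory=list)


def aging_trajectory(
    records: pd.DataFrame,
    contrasts: list[tuple[int, int]] | None = None,
) -> AgingResult:
    """Per-day means/SEMs of the transient metrics + omnibus and pairwise tests.

    One-way ANOVA across days on the peak (and slope); designated pairwise
    contrasts (default: consecutive observed days) with two-sided Welch
    tests.  Days with fewer than 2 analyzed worms are excluded and logged.
    """
    ok = _analyzed(records)
    counts = ok.groupby("age_day").size()
    excluded = [int(d) for d, n in counts.items() if n < 2]
    ok = ok[~ok["age_day"].isin(excluded)]
    days = sorted(ok["age_day"].unique())
    if len(days) < 2:
        raise ValueError("aging trajectory needs at least 2 days with n >= 2")

    per_day = []
    groups_peak, groups_slope = [], []
    for day in days:
        sub = ok[ok["age_day"] == day]
        peaks = sub["peak_pct"].to_numpy(float)
        slopes = sub["slope_pct_s"].to_numpy(float)
        groups_peak.append(peaks)
        groups_slope.append(slopes)
        per_day.append(
            {
                "age_day": int(day),
                "phase": phase_bin(int(day)),
                "n": len(sub),
                "mean_peak": peaks.mean(),
                "sem_peak": peaks.std(ddof=1) / math.sqrt(len(peaks)),
                "mean_slope": slopes.mean(),
                "sem_slope": slopes.std(ddof=1) / math.sqrt(len(slopes)),
            }
        )
    anova_p_peak = float(stats.f_oneway(*groups_peak).pvalue)
    anova_p_slope = float(stats.f_oneway(*groups_slope).pvalue)

    if contrasts is None:
        contrasts = list(zip(days[1:], days[:-1]))
    rows = []
    for da, db in contrasts:
        if da not in days or db not in days:
            continue
        a = ok.loc[ok["age_day"] == da, "peak_pct"].to_numpy(float)
        b = ok.loc[ok["age_day"] == db, "peak_pct"].to_numpy(float)
        _, _, p = welch_test(a, b)
        rows.append({"day_a": int(da), "day_b": int(db), "p_peak": p,
                     "diff_mean_peak": float(a.mean() - b.mean())})
    return AgingResult(pd.DataFrame(per_day), anova_p_peak, anova_p_slope,
                       pd.DataFrame(rows), excluded)


@dataclass
class TimecourseResult:
    anova: pd.DataFrame
    per_day: pd.DataFrame
    dropped_days: list[int] = field(default_factory=list)


def two_group_timecourse(
    records: pd.DataFrame,
    group_col: str = "group",
    alpha: float = 0.05,
) -> TimecourseResult:
    """Treated-vs-control comparison across days.

    Two-way (day x treatment) ANOVA on the peak, then per-day two-sided
    Welch comparisons with Bonferroni correction over the number of days.
    Days missing either group are dropped and logged; a single day
    degenerates to the plain two-group comparison (Bonferroni factor 1).
    """
    ok = _analyzed(records).copy()
    groups = sorted(ok[group_col].unique())
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    complete, dropped = [], []
    for day, sub in ok.groupby("age_day"):
        if all((sub[group_col] == g).sum() >= 2 for g in groups):
            complete.append(int(day))
        else:
            dropped.append(int(day))
    ok = ok[ok["age_day"].isin(complete)]
    if not complete:
        raise ValueError("no day has both groups with n >= 2")

    if len(complete) >= 2:
        model = ols(f"peak_pct ~ C(age_day) * C({group_col})", data=ok).fit()
        table = anova_lm(model, typ=2)
        anova = pd.DataFrame(
            {
                "factor": ["age_day", group_col, "interaction"],
                "p_value": [
                    float(table.loc[f"C(age_day)", "PR(>F)"]),
                    float(table.loc[f"C({group_col})", "PR(>F)"]),
                    float(table.loc[f"C(age_day):C({group_col})", "PR(>F)"]),
                ],
            }
        )
    else:
        anova = pd.DataFrame({"factor": [], "p_value": []})

    m = len(complete)
    rows = []
    for day in complete:
        sub = ok[ok["age_day"] == day]
        a = sub.loc[sub[group_col] == groups[1], "peak_pct"].to_numpy(float)
        b = sub.loc[sub[group_col] == groups[0], "peak_pct"].to_numpy(float)
        # convention: later-sorted group label (e.g. "treated") vs first ("control")
        _, _, p = welch_test(a, b)
        p_bonf = min(1.0, p * m)
        rows.append(
            {
                "age_day": day,
                "phase": phase_bin(day),
                "effect_pct": 100.0 * (a.mean() - b.mean()) / b.mean() if b.mean() > 0 else np.nan,
                "p_raw": p,
                "p_bonferroni": p_bonf,
                "significant": p_bonf < alpha,
            }
        )
    return TimecourseResult(anova, pd.DataFrame(rows), dropped)


@dataclass
class DoseResponseResult:
    per_dose: pd.DataFrame
    anova_p: float


def dose_response(records: pd.DataFrame, alpha: float = 0.05) -> DoseResponseResult:
    """Per-dose summaries + one-way ANOVA with pairwise tests vs vehicle (0 uM)."""
    ok = _analyzed(records)
    doses = sorted(ok["concentration_uM"].unique())
    if 0.0 not in doses:
        raise ValueError("dose-response analysis requires a vehicle (0 uM) group")
    if len(doses) < 2:
        raise ValueError("need at least 2 dose groups")
    vehicle = ok.loc[ok["concentration_uM"] == 0.0, "peak_pct"].to_numpy(float)
    groups = [ok.loc[ok["concentration_uM"] == d, "peak_pct"].to_numpy(float) for d in doses]
    anova_p = float(stats.f_oneway(*groups).pvalue)
    rows = []
    for d, g in zip(doses, groups):
        row = {
            "concentration_uM": d,
            "n": g.size,
            "mean_peak": g.mean(),
            "sem_peak": g.std(ddof=1) / math.sqrt(g.size) if g.size >= 2 else np.nan,
        }
        if d == 0.0:
            row.update(p_vs_vehicle=np.nan, significant=False)
        else:
            _, _, p = welch_test(g, vehicle)
            row.update(p_vs_vehicle=p, significant=p < alpha)
        rows.append(row)
    return DoseResponseResult(pd.DataFrame(rows), anova_p)
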