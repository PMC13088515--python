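"""Fertility phenotypes of risk matings.

Matings are classified per candidate region into risk1 (carrier sire x
genotyped carrier dam), risk2 (carrier sire x ungenotyped dam whose sire —
the maternal grandsire — is a carrier), and non-risk (non-carrier sire with
the same dam groups); independently every mating gets a sire-level label.
Three phenotypes are computed from the raw records: insemination success
(re-matings within 10 days collapsed into one event), stillbirth rate, and
juvenile mortality (death within 365 days of birth).  Group contrasts use a
pooled two-proportion z-test and are reported as relative differences in %.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest

logger = logging.getLogger(__name__)

CARRIER = frozenset({"carrier", "homozygous"})


def _to_days(series: pd.Series) -> pd.Series:
    """Normalize a date column to integer days (accepts ints or date strings)."""
    if pd.api.types.is_numeric_dtype(series):
        return series.astype("float64")
    dt = pd.to_datetime(series, errors="coerce")
    return (dt - pd.Timestamp("2000-01-01")).dt.days.astype("float64")


def _status_map(carrier_status) -> dict[str, str]:
    if isinstance(carrier_status, pd.DataFrame):
        return dict(zip(carrier_status["animal_id"], carrier_status["status"]))
    return dict(carrier_status)


# ---------------------------------------------------------------------------
# Classification
# ---------------------------------------------------------------------------


def classify_matings(matings: pd.DataFrame, carrier_status,
                     pedigree: pd.DataFrame | None = None) -> pd.DataFrame:
    """Label each mating with a risk category and a sire-level group.

    A dam with unknown genotype only enters through her sire (the maternal
    grandsire); a genotyped non-carrier dam never enters the grandsire-based
    groups even when the grandsire is a carrier, and a genotyped carrier dam
    contributes to risk1 only.  Matings whose sire has unknown status are
    excluded from every contrast (counted and logged).
    """
    status = _status_map(carrier_status)
    dam_sire = {}
    if pedigree is not None:
        dam_sire = dict(zip(pedigree["animal_id"], pedigree["sire_id"]))

    def lookup(animal: str) -> str:
        return status.get(animal, "unknown")

    categories = []
    sire_groups = []
    n_unknown_sires = 0
    for row in matings.itertuples(index=False):
        s, d = lookup(row.sire_id), lookup(row.dam_id)
        mgs_id = dam_sire.get(row.dam_id, "")
        mgs = lookup(mgs_id) if mgs_id else "unknown"

        if s in CARRIER:
            sire_group = "carrier-sire"
        elif s == "non-carrier":
            sire_group = "non-carrier-sire"
        else:
            sire_group = "unknown-sire"
            n_unknown_sires += 1
        sire_groups.append(sire_group)

        if d in CARRIER:
            dam_group = "dam-carrier"
        elif d == "non-carrier":
            dam_group = "dam-non-carrier"
        elif mgs in CARRIER:
            dam_group = "mgs-carrier"
        else:
            dam_group = "other"

        if sire_group == "carrier-sire":
            if dam_group == "dam-carrier":
                cat = "risk1"
            elif dam_group == "mgs-carrier":
                cat = "risk2"
            else:
                cat = "none"
        elif sire_group == "non-carrier-sire":
            cat = "non-risk" if dam_group in ("dam-carrier", "mgs-carrier") else "none"
        else:
            cat = "excluded"
        categories.append(cat)

    if n_unknown_sires:
        logger.info("excluded %d matings with unknown sire status", n_unknown_sires)
    out = matings.copy()
    out["category"] = categories
    out["sire_group"] = sire_groups
    return out


# ---------------------------------------------------------------------------
# Phenotypes
# ---------------------------------------------------------------------------


def collapse_rematings(matings: pd.DataFrame,
                       remating_window: int = 10) -> pd.DataFrame:
    """Collapse re-matings of a sire-dam pair into insemination events.

    A mating within ``remating_window`` days of the prior retained mating of
    the same pair joins that event (chains are transitive); the event keeps
    the first date.  Returns one row per event, carrying the attributes of
    the chain's first mating.
    """
    df = matings.copy()
    df["date"] = _to_days(df["date"])
    df = df.sort_values(["sire_id", "dam_id", "date"], kind="stable")
    gap = df.groupby(["sire_id", "dam_id"], sort=False)["date"].diff()
    new_event = gap.isna() | (gap > remating_window)
    df["event_id"] = new_event.cumsum()
    events = df.groupby("event_id", sort=False).first().reset_index()
    return events


def attribute_foals(events: pd.DataFrame, foals: pd.DataFrame,
                    gestation_window: tuple[int, int] = (300, 400)
                    ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Attribute each foal to the latest insemination event of its dam
    ``gestation_window`` days before birth.

    Returns (events with a ``success`` flag and attributed foal id, foals
    with the attributed ``event_id`` — NaN for orphans, which are logged).
    """
    lo, hi = gestation_window
    events = events.copy()
    foals = foals.copy()
    foals["birth_date"] = _to_days(foals["birth_date"])
    events["success"] = False
    events["foal_id"] = ""
    foals["event_id"] = np.nan

    by_dam: dict[str, pd.DataFrame] = {
        dam: sub.sort_values("date") for dam, sub in events.groupby("dam_id", sort=False)}
    n_orphans = 0
    for i, foal in foals.iterrows():
        sub = by_dam.get(foal["dam_id"])
        if sub is not None:
            window = sub[(sub["date"] >= foal["birth_date"] - hi)
                         & (sub["date"] <= foal["birth_date"] - lo)]
            if len(window):
                ev = window.index[-1]
                events.loc[ev, "success"] = True
                events.loc[ev, "foal_id"] = foal["foal_id"]
                foals.loc[i, "event_id"] = events.loc[ev, "event_id"]
                continue
        n_orphans += 1
    if n_orphans:
        logger.info("%d foals without a matching insemination event", n_orphans)
    return events, foals


def insemination_success(matings: pd.DataFrame, foals: pd.DataFrame, *,
                         remating_window: int = 10,
                         gestation_window: tuple[int, int] = (300, 400)
                         ) -> tuple[int, int]:
    """(successes, events): events producing a reported foal, dead or alive."""
    events = collapse_rematings(matings, remating_window)
    events, _ = attribute_foals(events, foals, gestation_window)
    return int(events["success"].sum()), len(events)


def stillbirth_rate(foals: pd.DataFrame) -> tuple[int, int]:
    """(stillbirths, foals): reported dead at birth or dying on the birth day."""
    birth = _to_days(foals["birth_date"])
    death = _to_days(foals["death_date"]) if "death_date" in foals else \
        pd.Series(np.nan, index=foals.index)
    flag = foals["dead_at_birth"].astype(bool) if "dead_at_birth" in foals else \
        pd.Series(False, index=foals.index)
    still = flag | (death == birth)
    return int(still.sum()), len(foals)


def juvenile_mortality(foals: pd.DataFrame) -> tuple[int, int]:
    """(deaths, foals): death within 365 days of birth, day-0 deaths included."""
    birth = _to_days(foals["birth_date"])
    death = _to_days(foals["death_date"]) if "death_date" in foals else \
        pd.Series(np.nan, index=foals.index)
    died = (death - birth) <= 365
    return int(died.fillna(False).sum()), len(foals)


# ---------------------------------------------------------------------------
# Contrast statistics
# ---------------------------------------------------------------------------


def two_proportion_ztest(x1: int, n1: int, x2: int, n2: int) -> tuple[float, float]:
    """Pooled-variance two-proportion z statistic and two-tailed p-value.

    Zero pooled variance (both rates 0 or both 1) yields (0, 1) by convention.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("group sizes must be positive")
    if not (0 <= x1 <= n1 and 0 <= x2 <= n2):
        raise ValueError("successes must lie in [0, n]")
    pooled = (x1 + x2) / (n1 + n2)
    if pooled in (0.0, 1.0):
        return 0.0, 1.0
    z, p = proportions_ztest([x1, x2], [n1, n2], alternative="two-sided")
    return float(z), float(p)


def relative_difference(rate_ref: float, rate_cmp: float) -> float:
    """Relative difference in %, ``(ref - cmp) / ref * 100``."""
    if rate_ref <= 0:
        raise ValueError("reference rate must be positive")
    return (rate_ref - rate_cmp) / rate_ref * 100.0


def expected_sire_reduction(carrier_freq: float) -> float:
    """Expected % reduction in insemination success for carrier-sire matings.

    Under full embryonic lethality a carrier sire loses a conception when the
    dam is also a carrier (probability = population carrier frequency) and
    the conception is homozygous (1/4): ``0.25 * carrier_freq * 100``.
    """
    if not 0 <= carrier_freq <= 1:
        raise ValueError("carrier frequency must be in [0, 1]")
    return 0.25 * carrier_freq * 100.0


# ---------------------------------------------------------------------------
# Category table
# ---------------------------------------------------------------------------

#: (category, reference) contrasts reported per region
CONTRASTS = (("risk1", "non-risk"), ("risk2", "non-risk"),
             ("carrier-sire", "non-carrier-sire"))


@dataclass
class CategoryStats:
    n_events: int
    successes: int
    n_foals: int
    stillbirths: int
    juvenile_deaths: int

    @property
    def insemination_rate(self) -> float:
        return self.successes / self.n_events if self.n_events else float("nan")


def build_category_table(matings: pd.DataFrame, foals: pd.DataFrame,
                         carrier_status, pedigree: pd.DataFrame | None = None, *,
                         remating_window: int = 10,
                         gestation_window: tuple[int, int] = (300, 400)
                         ) -> pd.DataFrame:
    """Per-category fertility phenotypes with contrasts against the reference.

    Rows cover risk1 / risk2 / non-risk and the sire-level carrier /
    non-carrier groups; ``rel_diff_pct`` is the relative drop in insemination
    success of each risk group against its reference (positive = worse), with
    the pooled z statistic and two-tailed p.  Rates are percentages.
    """
    labeled = classify_matings(matings, carrier_status, pedigree)
    events = collapse_rematings(labeled, remating_window)
    events, foal_tab = attribute_foals(events, foals, gestation_window)

    def stats_for(mask: pd.Series) -> CategoryStats:
        ev = events[mask]
        ev_ids = set(ev["event_id"])
        fo = foal_tab[foal_tab["event_id"].isin(ev_ids)]
        sb, nf = stillbirth_rate(fo) if len(fo) else (0, 0)
        jm, _ = juvenile_mortality(fo) if len(fo) else (0, 0)
        return CategoryStats(len(ev), int(ev["success"].sum()), nf, sb, jm)

    groups = {
        "risk1": stats_for(events["category"] == "risk1"),
        "risk2": stats_for(events["category"] == "risk2"),
        "non-risk": stats_for(events["category"] == "non-risk"),
        "carrier-sire": stats_for(events["sire_group"] == "carrier-sire"),
        "non-carrier-sire": stats_for(events["sire_group"] == "non-carrier-sire"),
    }

    rows = []
    refs = dict(CONTRASTS)
    for name, st in groups.items():
        row = {
            "category": name,
            "n_matings": st.n_events,
            "successes": st.successes,
            "insemination_success_pct": round(100 * st.insemination_rate, 1)
            if st.n_events else np.nan,
            "n_foals": st.n_foals,
            "stillbirth_pct": round(100 * st.stillbirths / st.n_foals, 1)
            if st.n_foals else np.nan,
            "juvenile_mortality_pct": round(100 * st.juvenile_deaths / st.n_foals, 1)
            if st.n_foals else np.nan,
        }
        ref_name = refs.get(name)
        if ref_name is not None:
            ref = groups[ref_name]
            if st.n_events and ref.n_events and ref.insemination_rate > 0:
                row["rel_diff_pct"] = round(relative_difference(
                    ref.insemination_rate, st.insemination_rate), 1)
                z, p = two_proportion_ztest(ref.successes, ref.n_events,
                                            st.successes, st.n_events)
                row["z"] = z
                row["p"] = p
        rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Semen quality
# ---------------------------------------------------------------------------


def compare_semen_quality(values_by_sire: pd.DataFrame,
                          carrier_flags) -> pd.DataFrame:
    """Carrier vs non-carrier comparison of semen-quality parameters.

    ``values_by_sire`` is sires x parameters; ``carrier_flags`` maps sire id
    to carrier (truthy).  Each parameter gets a two-sided Wilcoxon rank-sum
    (Mann-Whitney) test on the group values plus medians/IQRs; p-values are
    Bonferroni-corrected across the parameters tested.  A parameter with an
    empty group is skipped with a warning.
    """
    flags = dict(carrier_flags)
    carriers = [s for s in values_by_sire.index if flags.get(s)]
    noncarriers = [s for s in values_by_sire.index if s in flags and not flags[s]]

    rows = []
    for param in values_by_sire.columns:
        x = values_by_sire.loc[carriers, param].dropna().to_numpy()
        y = values_by_sire.loc[noncarriers, param].dropna().to_numpy()
        if len(x) == 0 or len(y) == 0:
            warnings.warn(f"semen parameter {param!r}: empty group, skipped",
                          stacklevel=2)
            continue
        pooled = np.concatenate([x, y])
        exact_ok = (max(len(x), len(y)) <= 25
                    and len(np.unique(pooled)) == len(pooled))
        res = stats.mannwhitneyu(x, y, alternative="two-sided",
                                 method="exact" if exact_ok else "auto")
        q1x, q3x = np.percentile(x, [25, 75])
        q1y, q3y = np.percentile(y, [25, 75])
        rows.append({
            "parameter": param,
            "n_carrier": len(x), "n_non_carrier": len(y),
            "median_carrier": float(np.median(x)),
            "iqr_carrier": float(q3x - q1x),
            "median_non_carrier": float(np.median(y)),
            "iqr_non_carrier": float(q3y - q1y),
            "p": float(res.pvalue),
        })
    table = pd.DataFrame(rows)
    if len(table):
        table["p_adj"] = np.minimum(1.0, table["p"] * len(table))
    return table
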