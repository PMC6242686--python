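"""Physiological indices, genotype-level statistics and vigour ranking.

This module turns per-plant trait records into the genotype comparison
table used to rank early vigour: per-genotype trait means (after Tukey
outlier screening), one-way ANOVA per trait with s.e.d. and LSD columns,
Pearson correlation matrices with significance stars, and the two
physiological indices

* eWUE — estimated water use efficiency, EB (kPix) divided by the total
  water supplied to the pot (kg);
* NDVI — (R760 - R670) / (R760 + R670), the normalised difference
  vegetation index from red (670 nm) and near-infrared (760 nm) canopy
  reflectance.

Genotypes are ranked by measured shoot biomass (MB) when a destructive
harvest is supplied, otherwise by EB; ties break by EB then by name.
Correlation p-values are reported unadjusted by default; Holm correction
is available as an option.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .growth import GrowthSeries, detect_outliers, rgr

logger = logging.getLogger("peavigour.vigour")

__all__ = [
    "WaterLog",
    "ReflectanceRecord",
    "PearsonResult",
    "AnovaResult",
    "VigourTable",
    "ewue",
    "ndvi",
    "significance_stars",
    "pearson_matrix",
    "one_way_anova",
    "rank_genotypes",
]

#: traits aggregated into the vigour table when present in the input
RANKED_TRAITS = ("mb_g", "eb_kpix", "tva_kpix", "tvch_kpix", "tvcom", "eh_pix", "rgr", "ewue")


@dataclass(frozen=True)
class WaterLog:
    """Total water supplied to one pot over the experiment (kg)."""

    plant_id: str
    total_water_kg: float

    def __post_init__(self) -> None:
        if not self.total_water_kg > 0:
            raise ValueError("total_water_kg must be positive")


@dataclass(frozen=True)
class ReflectanceRecord:
    """Two-band canopy reflectance for one field plot (fractions in [0, 1])."""

    plot_id: str
    genotype: str
    r670: float
    r760: float

    def __post_init__(self) -> None:
        for name in ("r670", "r760"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.r670 + self.r760 <= 0:
            raise ValueError("r670 + r760 must be positive")


def ewue(eb_kpix: float, water: "WaterLog | float") -> float:
    """Estimated water use efficiency: EB (kPix) per kg of supplied water."""
    w = water.total_water_kg if isinstance(water, WaterLog) else float(water)
    if not w > 0:
        raise ValueError("water amount must be positive")
    return float(eb_kpix) / w


def ndvi(record: "ReflectanceRecord | tuple[float, float]") -> float:
    """Normalised difference vegetation index (R760 - R670)/(R760 + R670)."""
    if isinstance(record, ReflectanceRecord):
        r670, r760 = record.r670, record.r760
    else:
        r760, r670 = record
    denom = r760 + r670
    if denom == 0:
        raise ValueError("R760 + R670 must be non-zero")
    return (r760 - r670) / denom


def significance_stars(p: float) -> str:
    if np.isnan(p):
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass
class PearsonResult:
    """Pairwise Pearson correlations with two-sided p-values and stars.

    Pairs are computed on pairwise-complete observations; ``n`` records the
    number of complete rows used for each pair.  Zero-variance columns
    yield NaN entries (with a warning), never a crash.
    """

    r: pd.DataFrame
    p: pd.DataFrame
    stars: pd.DataFrame
    n: pd.DataFrame
    holm_adjusted: bool = False


def pearson_matrix(table: pd.DataFrame, holm: bool = False) -> PearsonResult:
    """Product-moment correlation matrix over the columns of ``table``.

    p-values use the t transform with n - 2 degrees of freedom.  With
    ``holm=True`` the off-diagonal p-values are Holm-adjusted before
    starring.
    """
    cols = list(table.columns)
    k = len(cols)
    r = pd.DataFrame(np.eye(k), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((k, k)), index=cols, columns=cols)
    n = pd.DataFrame(np.zeros((k, k), dtype=int), index=cols, columns=cols)
    np.fill_diagonal(n.values, len(table))
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            sub = table[[cols[i], cols[j]]].dropna()
            n.iloc[i, j] = n.iloc[j, i] = len(sub)
            if len(sub) < 3:
                raise ValueError(
                    f"pair ({cols[i]}, {cols[j]}) has {len(sub)} complete rows; need >= 3"
                )
            x, y = sub.iloc[:, 0].to_numpy(), sub.iloc[:, 1].to_numpy()
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"zero-variance column in pair ({cols[i]}, {cols[j]}); r undefined",
                    stacklevel=2,
                )
                rij, pij = np.nan, np.nan
            else:
                rij, pij = sps.pearsonr(x, y)
            r.iloc[i, j] = r.iloc[j, i] = rij
            p.iloc[i, j] = p.iloc[j, i] = pij
            pairs.append((i, j))
    if holm:
        raw = np.array([p.iloc[i, j] for i, j in pairs])
        order = np.argsort(raw)
        m = len(raw)
        adj = np.empty(m)
        running = 0.0
        for rank, idx in enumerate(order):
            running = max(running, (m - rank) * raw[idx])
            adj[idx] = min(running, 1.0)
        for (i, j), a in zip(pairs, adj):
            p.iloc[i, j] = p.iloc[j, i] = a
    stars = p.map(significance_stars)
    for c in cols:
        stars.loc[c, c] = ""
    return PearsonResult(r=r, p=p, stars=stars, n=n, holm_adjusted=holm)


@dataclass
class AnovaResult:
    """One-way ANOVA summary with the pairwise-comparison columns.

    ``sed`` is the standard error of a difference between two group means,
    sqrt(2 MSE / n); ``lsd`` the least significant difference at 5%,
    t(0.975, df_error) * sed.  For unbalanced input n is the harmonic mean
    group size (warned).  When MSE is zero the F ratio degenerates: with
    any between-group spread F is +inf and p is 0; with none, F and p are
    NaN.
    """

    f: float
    p: float
    sed: float
    lsd: float
    df_between: int
    df_error: int
    ms_error: float
    balanced: bool


def one_way_anova(groups: Mapping[str, Sequence[float]]) -> AnovaResult:
    """Standard one-way ANOVA decomposition across genotype groups."""
    arrays = {k: np.asarray(v, dtype=float) for k, v in groups.items()}
    if len(arrays) < 2:
        raise ValueError("ANOVA needs at least 2 groups")
    if any(len(a) < 2 for a in arrays.values()):
        raise ValueError("every group needs at least 2 observations")
    sizes = np.array([len(a) for a in arrays.values()])
    all_values = np.concatenate(list(arrays.values()))
    grand = all_values.mean()
    ss_between = float(sum(len(a) * (a.mean() - grand) ** 2 for a in arrays.values()))
    ss_within = float(sum(((a - a.mean()) ** 2).sum() for a in arrays.values()))
    df_b = len(arrays) - 1
    df_e = len(all_values) - len(arrays)
    ms_b = ss_between / df_b
    ms_e = ss_within / df_e
    if ms_e == 0.0:
        f = np.inf if ms_b > 0 else np.nan
        p = 0.0 if ms_b > 0 else np.nan
    else:
        f = ms_b / ms_e
        p = float(sps.f.sf(f, df_b, df_e))
    balanced = bool(np.all(sizes == sizes[0]))
    n_eff = float(sizes[0]) if balanced else len(sizes) / float((1.0 / sizes).sum())
    if not balanced:
        warnings.warn(
            "unbalanced groups: s.e.d./LSD use the harmonic mean group size",
            stacklevel=2,
        )
    sed = float(np.sqrt(2.0 * ms_e / n_eff))
    lsd = float(sps.t.ppf(0.975, df_e) * sed)
    return AnovaResult(
        f=float(f), p=p, sed=sed, lsd=lsd,
        df_between=df_b, df_error=df_e, ms_error=ms_e, balanced=balanced,
    )


@dataclass
class VigourTable:
    """Genotype comparison table with ranks, ANOVA columns and correlations.

    ``table`` holds one row per genotype (rank, replicate count, trait
    means); ``anova`` one row per trait (F, p, s.e.d., LSD); and
    ``ndvi_correlations`` the field-validation Pearson r of genotype-mean
    NDVI against EB and TVA when reflectance records were supplied.
    """

    table: pd.DataFrame
    anova: pd.DataFrame
    comparison_day: int
    ndvi_correlations: pd.DataFrame | None = None


def _screened(values: np.ndarray) -> np.ndarray:
    """Drop Tukey-fence outliers when enough replicates are available."""
    values = values[~np.isnan(values)]
    if len(values) >= 4:
        return values[~detect_outliers(values)]
    return values


def rank_genotypes(
    traits: pd.DataFrame,
    comparison_day: int,
    water: Iterable[WaterLog] | None = None,
    reflectance: Iterable[ReflectanceRecord] | None = None,
    measured_biomass: pd.DataFrame | None = None,
    rgr_interval: tuple[float, float] | None = None,
) -> VigourTable:
    """Build the genotype-level early-vigour comparison table.

    Parameters
    ----------
    traits : DataFrame
        Per-plant trait records with columns ``plant_id, genotype, das,
        eb_kpix`` and optionally ``tva_kpix, tvch_kpix, tvcom, eh_pix``.
        Rows are taken at ``comparison_day`` (normally the linear-phase
        onset day); genotypes absent on that day are dropped with a logged
        warning.  Rows with NaN EB (flagged plant-days) are excluded.
    comparison_day : int
        The common DAS at which genotypes are compared.
    water : iterable of WaterLog, optional
        Per-pot water totals; enables the eWUE column.
    reflectance : iterable of ReflectanceRecord, optional
        Field reflectance; enables NDVI-vs-EB/TVA correlations.
    measured_biomass : DataFrame, optional
        Columns ``plant_id, genotype, mb_g`` from a destructive harvest
        (at a later day than ``comparison_day``); enables the MB column
        and makes MB the ranking key.
    rgr_interval : (t1, t2), optional
        Day pair for the RGR column, computed from per-replicate EB via
        the mean-of-logs formula.
    """
    required = {"plant_id", "genotype", "das", "eb_kpix"}
    missing = required - set(traits.columns)
    if missing:
        raise ValueError(f"trait table missing columns: {sorted(missing)}")

    at_day = traits[traits["das"] == comparison_day]
    n_bad = int(at_day["eb_kpix"].isna().sum())
    if n_bad:
        logger.warning("excluding %d flagged plant-days at DAS %d", n_bad, comparison_day)
        at_day = at_day[at_day["eb_kpix"].notna()]
    dropped = sorted(set(traits["genotype"]) - set(at_day["genotype"]))
    if dropped:
        logger.warning("genotypes missing at DAS %d dropped: %s", comparison_day, dropped)
    if at_day.empty:
        raise ValueError(f"no usable trait records at DAS {comparison_day}")

    water_by_plant = {w.plant_id: w.total_water_kg for w in water} if water else {}
    trait_cols = [c for c in ("eb_kpix", "tva_kpix", "tvch_kpix", "tvcom", "eh_pix")
                  if c in at_day.columns]

    per_genotype: dict[str, dict[str, float]] = {}
    groups: dict[str, dict[str, np.ndarray]] = {c: {} for c in trait_cols + ["ewue", "mb_g"]}
    for genotype, sub in at_day.groupby("genotype", sort=True):
        row: dict[str, float] = {"n_reps": len(sub)}
        for c in trait_cols:
            vals = _screened(sub[c].to_numpy(dtype=float))
            row[c] = float(vals.mean()) if len(vals) else np.nan
            groups[c][genotype] = vals
        if water_by_plant:
            wu = np.array([
                ewue(e, water_by_plant[p])
                for p, e in zip(sub["plant_id"], sub["eb_kpix"])
                if p in water_by_plant
            ])
            wu = _screened(wu)
            row["ewue"] = float(wu.mean()) if len(wu) else np.nan
            groups["ewue"][genotype] = wu
        per_genotype[genotype] = row

    if measured_biomass is not None:
        for genotype, sub in measured_biomass.groupby("genotype"):
            if genotype in per_genotype:
                vals = _screened(sub["mb_g"].to_numpy(dtype=float))
                per_genotype[genotype]["mb_g"] = float(vals.mean()) if len(vals) else np.nan
                groups["mb_g"][genotype] = vals

    if rgr_interval is not None:
        t1, t2 = rgr_interval
        for genotype in per_genotype:
            reps = []
            for plant_id, sub in traits[traits["genotype"] == genotype].groupby("plant_id"):
                sub = sub.sort_values("das")
                ok = sub["eb_kpix"].notna()
                if {t1, t2} <= set(sub.loc[ok, "das"]) and len(sub[ok]) >= 5:
                    reps.append(GrowthSeries(genotype, plant_id,
                                             sub.loc[ok, "das"].to_numpy(dtype=float),
                                             sub.loc[ok, "eb_kpix"].to_numpy(dtype=float)))
            per_genotype[genotype]["rgr"] = rgr(reps, t1, t2) if reps else np.nan

    table = pd.DataFrame.from_dict(per_genotype, orient="index")
    table.index.name = "genotype"

    key = "mb_g" if "mb_g" in table.columns else "eb_kpix"
    names = np.array([str(g) for g in table.index])
    idx = np.lexsort(  # primary: key desc; ties: EB desc, then name asc
        (names, -table["eb_kpix"].to_numpy(), -table[key].to_numpy())
    )
    table = table.iloc[idx]
    table.insert(0, "rank", np.arange(1, len(table) + 1))

    anova_rows = {}
    for c, by_geno in groups.items():
        usable = {g: v for g, v in by_geno.items() if len(v) >= 2}
        if len(usable) >= 2:
            res = one_way_anova(usable)
            anova_rows[c] = {"f": res.f, "p": res.p, "sed": res.sed, "lsd": res.lsd}
    anova = pd.DataFrame.from_dict(anova_rows, orient="index")
    anova.index.name = "trait"

    ndvi_corr = None
    if reflectance is not None:
        recs = list(reflectance)
        nd = pd.Series(
            [ndvi(r) for r in recs], index=[r.genotype for r in recs], dtype=float
        ).groupby(level=0).mean()
        rows = {}
        for c, label in (("eb_kpix", "EB"), ("tva_kpix", "TVA")):
            if c in table.columns:
                joined = pd.concat([table[c], nd.rename("ndvi")], axis=1, join="inner").dropna()
                if len(joined) >= 3:
                    rv, pv = sps.pearsonr(joined[c], joined["ndvi"])
                    rows[label] = {"r": rv, "p": pv, "stars": significance_stars(pv),
                                   "n": len(joined)}
        ndvi_corr = pd.DataFrame.from_dict(rows, orient="index") if rows else None

    return VigourTable(
        table=table, anova=anova, comparison_day=comparison_day,
        ndvi_correlations=ndvi_corr,
    )
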