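"""Paired enrichment testing of small RNA count data.

Implements the count-model workflow used for the Ψ-IP (bound vs
unbound) and CMC (treated vs mock) contrasts: median-of-ratios library
normalization, method-of-moments negative-binomial dispersion with
shrinkage toward a mean-expression trend, a Wald test on the log
fold change under the NB model, and Benjamini–Hochberg adjustment.

Features are unique insert sequences or annotated aggregates (e.g. all
sequences of one locus); libraries carry condition, pair and replicate
metadata. Technical replicates of one biological replicate are averaged
before testing.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .reads_io import CollapsedRead

logger = logging.getLogger("psifinder.enrich")

META_COLUMNS = ("assay", "condition", "pair", "replicate", "tech")


@dataclass
class CountMatrix:
    """Integer counts (features × libraries) with library metadata."""

    counts: pd.DataFrame
    meta: pd.DataFrame
    annot: pd.DataFrame | None = None

    def validate(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("count matrix contains negative entries")
        if not self.counts.index.is_unique:
            raise ValueError("feature ids are not unique")
        missing = set(self.counts.columns) - set(self.meta.index)
        if missing:
            raise ValueError(f"libraries missing from metadata: {sorted(missing)}")
        for col in ("condition", "pair"):
            if self.meta.loc[list(self.counts.columns), col].isna().any():
                raise ValueError(f"every library needs a {col}")


def metadata_from_sim(sim_result) -> pd.DataFrame:
    """Library metadata sheet from a :class:`~psifinder.simdata.SimResult`."""
    rows = [{"library": l.label, "assay": l.assay, "condition": l.assay,
             "pair": l.pair, "replicate": l.replicate, "tech": 1}
            for l in sim_result.libraries]
    return pd.DataFrame(rows).set_index("library")


def build_count_matrix(
    collapsed: Sequence[CollapsedRead],
    meta: pd.DataFrame,
    min_mean: float = 10.0,
    strict: bool = True,
    annot: pd.DataFrame | None = None,
    aggregate_by: str | None = None,
) -> CountMatrix:
    """Assemble the per-feature count matrix.

    With ``aggregate_by="features"`` counts are summed per annotated
    feature (a sequence matching several features contributes to each);
    otherwise the unique sequence is the feature. Features whose mean
    raw count across libraries is not greater than ``min_mean`` (or
    ``< min_mean`` with ``strict=False``) are removed; removals are
    logged.
    """
    libs = list(meta.index)
    unknown = {lib for c in collapsed for lib in c.counts} - set(libs)
    if unknown:
        raise ValueError(f"libraries missing from metadata: {sorted(unknown)}")
    rows: dict[str, dict[str, int]] = {}
    dropped_unannotated = 0
    for c in collapsed:
        if aggregate_by:
            if annot is None:
                raise ValueError("aggregation requires an annotation table")
            if c.sequence not in annot.index:
                dropped_unannotated += 1
                continue
            ids = [x for x in str(annot.loc[c.sequence, aggregate_by]).split(",") if x]
            if not ids:
                dropped_unannotated += 1
                continue
        else:
            ids = [c.sequence]
        for fid in ids:
            row = rows.setdefault(fid, {})
            for lib, n in c.counts.items():
                row[lib] = row.get(lib, 0) + n
    if dropped_unannotated:
        logger.info("dropped %d unannotated sequences", dropped_unannotated)
    counts = pd.DataFrame.from_dict(rows, orient="index", dtype=float).fillna(0.0)
    counts = counts.reindex(columns=libs, fill_value=0.0).sort_index().astype(int)
    if len(counts):
        means = counts.mean(axis=1)
        keep = means > min_mean if strict else means >= min_mean
        n_removed = int((~keep).sum())
        if n_removed:
            logger.info("min_mean filter removed %d/%d features", n_removed, len(counts))
        counts = counts.loc[keep]
    cm = CountMatrix(counts, meta, annot)
    cm.validate()
    return cm


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

def compute_size_factors(counts: pd.DataFrame, pseudo_reference: bool = False) -> pd.Series:
    """Median-of-ratios size factors.

    Per library, the median over features of count / (geometric mean of
    that feature across libraries), computed over features with nonzero
    counts in every library. ``pseudo_reference=True`` falls back to
    geometric means over positive entries only, rescuing matrices
    without any everywhere-nonzero feature.
    """
    arr = counts.to_numpy(dtype=float)
    if pseudo_reference:
        logs = np.full(arr.shape, np.nan)
        logs[arr > 0] = np.log(arr[arr > 0])
        with np.errstate(invalid="ignore"):
            loggeo = np.nanmean(logs, axis=1)
        usable = ~np.isnan(loggeo)
    else:
        usable = (arr > 0).all(axis=1)
        if not usable.any():
            raise ValueError(
                "no feature has nonzero counts in every library; "
                "re-run with pseudo_reference=True")
        loggeo = np.zeros(arr.shape[0])
        loggeo[usable] = np.log(arr[usable]).mean(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = arr[usable] / np.exp(loggeo[usable])[:, None]
    sf = np.nanmedian(np.where(ratios > 0, ratios, np.nan), axis=0)
    factors = pd.Series(sf, index=counts.columns, name="size_factor")
    gm = float(np.exp(np.log(factors).mean()))
    if not (0.5 <= gm <= 2.0):
        logger.warning("size factor geometric mean %.3f outside [0.5, 2]", gm)
    return factors


# ---------------------------------------------------------------------------
# Dispersion
# ---------------------------------------------------------------------------

def estimate_dispersion(
    counts: pd.DataFrame,
    size_factors: pd.Series,
    conditions: Mapping[str, str] | pd.Series,
    floor: float = 1e-8,
    shrink: float = 0.2,
    n_bins: int = 20,
) -> pd.Series:
    """Per-feature NB dispersion α with trend shrinkage.

    Method-of-moments (s² − μ)/μ² on normalized counts, pooled across
    conditions with at least two replicates, shrunk ``shrink`` of the
    way toward the mean of similarly expressed features (quantile bins
    of the normalized mean), and floored at ``floor``. The signed
    moment estimate enters both the per-feature value and the trend —
    flooring before averaging would bias α upward for near-Poisson
    data and make the Wald test conservative; only the final shrunk
    value is clipped. Without any replicated condition the trend cannot
    be anchored and a flat floor dispersion is returned with a warning.
    """
    conditions = pd.Series(conditions)
    norm = counts / size_factors.reindex(counts.columns)
    groups = [norm.loc[:, conditions[conditions == c].index]
              for c in conditions.unique()]
    groups = [g for g in groups if g.shape[1] >= 2]
    if not groups:
        logger.warning("no condition has >= 2 replicates; trend-only floor dispersion")
        return pd.Series(floor, index=counts.index, name="dispersion")
    num = np.zeros(len(counts))
    den = 0.0
    for g in groups:
        w = g.shape[1] - 1
        mu = g.mean(axis=1).to_numpy()
        var = g.var(axis=1, ddof=1).to_numpy()
        # shot-noise term of normalized counts is mu/s, not mu
        xi = float(np.mean(1.0 / size_factors.reindex(g.columns)))
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mu > 0, (var - mu * xi) / np.maximum(mu, 1e-300) ** 2, 0.0)
        num += w * a
        den += w
    alpha_mom = num / den  # signed; flooring happens after shrinkage
    base_mean = norm.mean(axis=1).to_numpy()
    order = np.argsort(base_mean, kind="stable")
    bins = max(1, min(n_bins, len(counts) // 5 or 1))
    trend = np.empty(len(counts))
    for chunk in np.array_split(order, bins):
        trend[chunk] = alpha_mom[chunk].mean()
    alpha = np.maximum(shrink * alpha_mom + (1.0 - shrink) * trend, floor)
    return pd.Series(alpha, index=counts.index, name="dispersion")


# ---------------------------------------------------------------------------
# Wald test
# ---------------------------------------------------------------------------

def bh_adjust(pvalues: Sequence[float] | np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(pvalues, dtype=float)
    n = len(p)
    if n == 0:
        return p
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(adj, 1.0)
    return out


def _tech_average(norm: pd.DataFrame, meta: pd.DataFrame, libs: list[str]):
    """Average technical replicates; returns (values, units) where each
    unit is the list of contributing library labels."""
    units: dict[tuple, list[str]] = {}
    for lib in libs:
        key = (meta.loc[lib, "condition"], meta.loc[lib, "pair"], meta.loc[lib, "replicate"])
        units.setdefault(key, []).append(lib)
    cols, mats = [], []
    for key in sorted(units, key=str):
        mats.append(norm.loc[:, units[key]].mean(axis=1))
        cols.append(key)
    return pd.concat(mats, axis=1, keys=range(len(cols))), [units[k] for k in sorted(units, key=str)]


def test_enrichment(
    cm: CountMatrix,
    size_factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str],
    paired: bool = False,
    pseudocount: float = 0.5,
) -> pd.DataFrame:
    """NB Wald test of ``contrast = (treated, reference)`` conditions.

    log2FC is the log2 ratio of normalized condition means with a
    pseudocount on the means; its standard error comes from the NB
    variance μ/s + αμ² of each contributing library, propagated through
    the log. Two-sided p-values use the normal reference; padj is
    Benjamini–Hochberg over the tested features. ``paired=True``
    switches to a pair-factor design (mean of per-pair log-ratios).
    """
    cm.validate()
    treated, reference = contrast
    meta = cm.meta
    t_libs = [l for l in cm.counts.columns if meta.loc[l, "condition"] == treated]
    r_libs = [l for l in cm.counts.columns if meta.loc[l, "condition"] == reference]
    if not t_libs or not r_libs:
        raise ValueError(f"contrast {contrast} not present in metadata")
    t_pairs = set(meta.loc[t_libs, "pair"])
    r_pairs = set(meta.loc[r_libs, "pair"])
    if t_pairs != r_pairs:
        raise ValueError(f"unmatched pair ids: {sorted(t_pairs ^ r_pairs)}")

    sf = size_factors.reindex(cm.counts.columns)
    norm = cm.counts / sf
    alpha = dispersions.reindex(cm.counts.index).to_numpy()
    pc = pseudocount

    def group_stats(libs: list[str]):
        vals, units = _tech_average(norm, meta, libs)
        m = vals.mean(axis=1).to_numpy()
        # plug-in mean for the NB variance; a small guard keeps the SE
        # finite for conditions observed at zero
        mu = np.maximum(m, 0.25)
        # Var of the mean of tech-averaged NB libraries at plug-in mean mu
        var = np.zeros(len(mu))
        for unit in units:
            v_unit = np.zeros(len(mu))
            for lib in unit:
                v_unit += mu / sf[lib] + alpha * mu ** 2
            var += v_unit / len(unit) ** 2
        var /= len(units) ** 2
        return vals, m, var, units

    t_vals, m_t, var_t, t_units = group_stats(t_libs)
    r_vals, m_r, var_r, r_units = group_stats(r_libs)
    base_mean = norm.loc[:, t_libs + r_libs].mean(axis=1).to_numpy()
    ln2 = np.log(2.0)

    if not paired:
        log2fc = np.log2((m_t + pc) / (m_r + pc))
        se = np.sqrt(var_t / (m_t + pc) ** 2 + var_r / (m_r + pc) ** 2) / ln2
    else:
        t_keys = {meta.loc[u[0], "pair"]: i for i, u in enumerate(t_units)}
        r_keys = {meta.loc[u[0], "pair"]: i for i, u in enumerate(r_units)}
        pairs = sorted(t_keys)
        d = np.zeros((len(cm.counts), len(pairs)))
        vard = np.zeros(len(cm.counts))
        mu_t, mu_r = np.maximum(m_t, 0.25), np.maximum(m_r, 0.25)
        for j, p_id in enumerate(pairs):
            xt = t_vals.iloc[:, t_keys[p_id]].to_numpy() + pc
            xr = r_vals.iloc[:, r_keys[p_id]].to_numpy() + pc
            d[:, j] = np.log(xt / xr)
            st = np.mean([sf[l] for l in t_units[t_keys[p_id]]])
            sr = np.mean([sf[l] for l in r_units[r_keys[p_id]]])
            vard += (mu_t / st + alpha * mu_t ** 2) / xt ** 2 / len(t_units[t_keys[p_id]])
            vard += (mu_r / sr + alpha * mu_r ** 2) / xr ** 2 / len(r_units[r_keys[p_id]])
        log2fc = d.mean(axis=1) / ln2
        se = np.sqrt(vard) / len(pairs) / ln2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(se > 0, log2fc / np.where(se > 0, se, 1.0), 0.0)
    pval = 2.0 * stats.norm.sf(np.abs(stat))
    res = pd.DataFrame({
        "baseMean": base_mean,
        "log2FC": log2fc,
        "lfcSE": se,
        "stat": stat,
        "pvalue": pval,
        "padj": bh_adjust(pval),
    }, index=cm.counts.index)
    res.index.name = "feature"
    return res
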