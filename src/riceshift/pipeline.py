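"""End-to-end orchestration: requirements -> fortification -> adequacy ->
CO2 scenario -> NTD burden -> Monte Carlo uncertainty.

The input bundle (eleven CSV tables) is compiled once into flat numpy
arrays over the strata (country x sex x 5-year age bin), after which a
single deterministic pass and every Monte Carlo draw run the same
vectorized computation.  The point estimate is the deterministic central
run; uncertainty intervals are the empirical middle 95% over draws in
which CO2 loss factors and NTD burdens are sampled from their matched
skew-normals and food-level supplies from normals with their reported
standard errors.  Draws that produce an inconsistent world (negative
supplies or burden) are rejected and redrawn; more than 10% rejections
aborts the run.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import adequacy, fortification, ntd, requirements, tables
from .model import NUTRIENTS, REPRO_AGE_BINS, RiceshiftError
from .uncertainty import MonteCarloConfig, SkewNormalParams, fit_skew_normal, percentile_interval

log = logging.getLogger(__name__)

INPUT_SCHEMAS: tuple[str, ...] = (
    "supplies", "population", "fertility", "breastfeeding", "requirements",
    "fortification", "loss_factors", "burden", "dose_response", "regions",
    "vehicle_intake",
)


def save_world(bundle: dict[str, pd.DataFrame], directory: str | Path) -> None:
    """Write every input table of a bundle into a directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in INPUT_SCHEMAS:
        tables.write_table(bundle[name], directory / f"{name}.csv", name)


def load_world(directory: str | Path) -> dict[str, pd.DataFrame]:
    """Read and validate a full input bundle from a directory."""
    directory = Path(directory)
    bundle = {}
    for name in INPUT_SCHEMAS:
        path = directory / f"{name}.csv"
        if not path.exists():
            raise FileNotFoundError(f"missing input table {path.name} in {directory}")
        bundle[name] = tables.read_table(path, name)
    return bundle


@dataclass(frozen=True)
class RunConfig:
    """Options of one pipeline run."""

    cv: float = 0.30
    degree: int = 2
    mc: MonteCarloConfig = field(default_factory=MonteCarloConfig)
    year_current: int = 2010
    year_future: int = 2050
    fortification: bool = True
    nutrients: tuple[str, ...] = NUTRIENTS


@dataclass
class CompiledWorld:
    """Input bundle flattened to arrays over strata (one row per stratum)."""

    strata: pd.DataFrame            # country, sex, age_low
    countries: list[str]
    regions: list[str]
    country_idx: np.ndarray         # per stratum -> index into countries
    region_idx: np.ndarray          # per stratum -> index into regions
    country_region_idx: np.ndarray  # per country -> index into regions
    pop_current: np.ndarray
    pop_future: np.ndarray
    nutrients: tuple[str, ...]
    rice: np.ndarray                # (n_nutrients, n_strata) pre-fortified
    nonrice: np.ndarray
    se_rice: np.ndarray
    se_nonrice: np.ndarray
    fort: np.ndarray
    ear: np.ndarray
    loss_mean: np.ndarray           # (n_nutrients,) mean frac change
    loss_sampler: list[SkewNormalParams]
    burden_mean: dict[str, np.ndarray]          # measure -> (n_countries,)
    burden_sampler: dict[str, list[SkewNormalParams]]
    curve: ntd.DoseResponseCurve
    repro_idx: np.ndarray           # strata indices of women 15-49
    birth_weights: np.ndarray       # ASFR x female population per repro stratum
    cv: float


def compile_world(bundle: dict[str, pd.DataFrame], config: RunConfig) -> CompiledWorld:
    """Precompute every per-stratum array the draw loop needs."""
    pop = bundle["population"]
    pop_cur = pop[pop["year"] == config.year_current]
    strata = pop_cur[["country", "sex", "age_low"]].drop_duplicates().sort_values(
        ["country", "sex", "age_low"], kind="mergesort"
    ).reset_index(drop=True)
    n_strata = len(strata)
    countries = sorted(strata["country"].unique())
    region_of = bundle["regions"].set_index("country")["region"]
    missing = set(countries) - set(region_of.index)
    if missing:
        raise RiceshiftError(f"countries missing from regions table: {sorted(missing)}")
    regions = sorted(set(region_of[c] for c in countries))
    country_pos = {c: i for i, c in enumerate(countries)}
    region_pos = {r: i for i, r in enumerate(regions)}
    country_idx = strata["country"].map(country_pos).to_numpy()
    region_idx = strata["country"].map(lambda c: region_pos[region_of[c]]).to_numpy()
    country_region_idx = np.array([region_pos[region_of[c]] for c in countries])

    key = ["country", "sex", "age_low"]
    stratum_key = pd.MultiIndex.from_frame(strata[key])

    def stratum_series(df: pd.DataFrame, value: str) -> np.ndarray:
        s = df.set_index(key)[value].reindex(stratum_key)
        return s.to_numpy(dtype=float)

    pop_current = stratum_series(pop_cur, "population")
    pop_future = stratum_series(pop[pop["year"] == config.year_future], "population")
    pop_current = np.nan_to_num(pop_current)
    pop_future = np.nan_to_num(pop_future)

    # supplies split into rice vs everything else, with combined SEs
    sup = bundle["supplies"].copy()
    sup["se"] = sup["se"].fillna(0.0)
    is_rice = sup["food"] == "rice"
    nn = len(config.nutrients)
    rice = np.zeros((nn, n_strata))
    nonrice = np.zeros((nn, n_strata))
    se_rice = np.zeros((nn, n_strata))
    se_nonrice = np.zeros((nn, n_strata))
    for ni, nutrient in enumerate(config.nutrients):
        sel = sup[sup["nutrient"] == nutrient]
        r = sel[is_rice.reindex(sel.index, fill_value=False)]
        o = sel[~is_rice.reindex(sel.index, fill_value=False)]
        rg = r.groupby(key)
        og = o.groupby(key)
        rice[ni] = np.nan_to_num(rg["supply"].sum().reindex(stratum_key).to_numpy(dtype=float))
        nonrice[ni] = np.nan_to_num(og["supply"].sum().reindex(stratum_key).to_numpy(dtype=float))
        se_rice[ni] = np.nan_to_num(
            np.sqrt(rg["se"].apply(lambda s: float((s**2).sum())).reindex(stratum_key).to_numpy(dtype=float))
        )
        se_nonrice[ni] = np.nan_to_num(
            np.sqrt(og["se"].apply(lambda s: float((s**2).sum())).reindex(stratum_key).to_numpy(dtype=float))
        )

    # fortification additions (zeros when the flag is off)
    fort = np.zeros((nn, n_strata))
    if config.fortification and len(bundle["fortification"]):
        added = fortification.stratum_added(
            bundle["fortification"], bundle["vehicle_intake"], bundle["supplies"],
            bundle["population"], year=config.year_current,
        )
        for ni, nutrient in enumerate(config.nutrients):
            a = added[added["nutrient"] == nutrient]
            fort[ni] = np.nan_to_num(
                a.set_index(key)["added"].reindex(stratum_key).to_numpy(dtype=float)
            )

    # per-stratum EARs
    ear_table = requirements.build_ear_table(
        bundle["requirements"], bundle["population"], bundle["fertility"],
        bundle["breastfeeding"], bundle["regions"], year=config.year_current,
    )
    ear = np.zeros((nn, n_strata))
    for ni, nutrient in enumerate(config.nutrients):
        e = ear_table[ear_table["nutrient"] == nutrient]
        ear[ni] = e.set_index(key)["ear"].reindex(stratum_key).to_numpy(dtype=float)

    # CO2 loss factors and their samplers
    lf = bundle["loss_factors"].set_index("nutrient")
    loss_mean = np.array([float(lf.loc[nu, "mean_frac_change"]) for nu in config.nutrients])
    loss_sampler = [
        fit_skew_normal(float(lf.loc[nu, "mean_frac_change"]), float(lf.loc[nu, "lo95"]),
                        float(lf.loc[nu, "hi95"]))
        for nu in config.nutrients
    ]

    bur = bundle["burden"].set_index(["country", "measure"])
    burden_mean = {}
    burden_sampler = {}
    for measure in ("deaths", "dalys"):
        burden_mean[measure] = np.array(
            [float(bur.loc[(c, measure), "mean"]) if (c, measure) in bur.index else 0.0
             for c in countries]
        )
        burden_sampler[measure] = [
            fit_skew_normal(
                float(bur.loc[(c, measure), "mean"]),
                float(bur.loc[(c, measure), "lo95"]),
                float(bur.loc[(c, measure), "hi95"]),
            )
            if (c, measure) in bur.index
            else SkewNormalParams(0.0, 0.0, 0.0)
            for c in countries
        ]

    dr = bundle["dose_response"]
    curve = ntd.fit_rr_curve(dr["intake"], dr["risk_per_1000"], degree=config.degree)

    # birth-weighted exposure strata: women 15-49
    asfr = bundle["fertility"].set_index(["country", "age_low"])["asfr"]
    mask = (strata["sex"] == "female") & strata["age_low"].isin(REPRO_AGE_BINS)
    repro_idx = np.flatnonzero(mask.to_numpy())
    birth_weights = np.array(
        [
            float(asfr.get((strata["country"].iloc[i], int(strata["age_low"].iloc[i])), 0.0))
            * pop_current[i]
            for i in repro_idx
        ]
    )

    return CompiledWorld(
        strata=strata, countries=countries, regions=regions,
        country_idx=country_idx, region_idx=region_idx,
        country_region_idx=country_region_idx,
        pop_current=pop_current, pop_future=pop_future,
        nutrients=tuple(config.nutrients),
        rice=rice, nonrice=nonrice, se_rice=se_rice, se_nonrice=se_nonrice,
        fort=fort, ear=ear, loss_mean=loss_mean, loss_sampler=loss_sampler,
        burden_mean=burden_mean, burden_sampler=burden_sampler, curve=curve,
        repro_idx=repro_idx, birth_weights=birth_weights, cv=config.cv,
    )


def _group_sums(values: np.ndarray, weights: np.ndarray, group: np.ndarray, n_groups: int):
    """Weighted sums of ``values`` by group, NaN treated as missing."""
    ok = ~np.isnan(values)
    return (
        np.bincount(group[ok], weights=(values * weights)[ok], minlength=n_groups),
        np.bincount(group[ok], weights=weights[ok], minlength=n_groups),
    )


def _scoped(cw: CompiledWorld, values: np.ndarray, weights: np.ndarray, kind: str) -> dict[str, float]:
    """Aggregate a stratum vector to every region plus 'global'.

    kind 'sum' adds value x weight; kind 'mean' is the weighted mean.
    """
    n_r = len(cw.regions)
    num, den = _group_sums(values, weights, cw.region_idx, n_r)
    out = {}
    for i, r in enumerate(cw.regions):
        out[r] = num[i] / den[i] if (kind == "mean" and den[i] > 0) else num[i]
        if kind == "mean" and den[i] == 0:
            out[r] = float("nan")
    total_num, total_den = num.sum(), den.sum()
    out["global"] = total_num / total_den if (kind == "mean" and total_den > 0) else total_num
    return out


def compute_draw(
    cw: CompiledWorld,
    rice: np.ndarray,
    nonrice: np.ndarray,
    frac_change: np.ndarray,
    burden: dict[str, np.ndarray],
    keep_strata: bool = False,
) -> tuple[dict[tuple[str, str, str], float], dict | None]:
    """One full deterministic pass over the compiled world.

    Returns ``{(scope, nutrient, metric): value}`` and, when requested,
    the per-stratum arrays needed for the audit CSVs.
    """
    frac_loss = -np.clip(frac_change, -1.0, 1.0)
    metrics: dict[tuple[str, str, str], float] = {}
    per_stratum = {} if keep_strata else None
    pif_by_country = None

    for ni, nutrient in enumerate(cw.nutrients):
        total = rice[ni] + nonrice[ni]
        fort = cw.fort[ni]
        m_cur = total + fort
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = (total - rice[ni] * frac_loss[ni] + fort) / m_cur
        valid = m_cur > 0
        ratio = np.where(valid, ratio, np.nan)
        m_e = m_cur * ratio
        prev_cur = adequacy.prevalence_inadequate_arr(m_cur, cw.ear[ni], cw.cv)
        prev_e = adequacy.prevalence_inadequate_arr(m_e, cw.ear[ni], cw.cv)
        delta = prev_e - prev_cur
        newly = delta * cw.pop_future
        already = prev_cur * cw.pop_future

        for metric, vals, weights, kind in (
            ("prevalence_current", prev_cur, cw.pop_current, "mean"),
            ("prevalence_eco2", prev_e, cw.pop_current, "mean"),
            ("newly_at_risk", newly, np.ones_like(newly), "sum"),
            ("already_deficient", already, np.ones_like(already), "sum"),
        ):
            for scope, v in _scoped(cw, vals, weights, kind).items():
                metrics[(scope, nutrient, metric)] = float(v)
        for scope in list(cw.regions) + ["global"]:
            metrics[(scope, nutrient, "delta_points")] = 100.0 * (
                metrics[(scope, nutrient, "prevalence_eco2")]
                - metrics[(scope, nutrient, "prevalence_current")]
            )
        # contribution of rice to total dietary supply (pre-CO2)
        share = np.where(m_cur > 0, rice[ni] / m_cur, np.nan)
        for scope, v in _scoped(cw, share, cw.pop_current * m_cur, "mean").items():
            metrics[(scope, nutrient, "rice_share_pct")] = float(100.0 * v)

        if keep_strata:
            per_stratum[nutrient] = {
                "mean_current": m_cur, "ratio": ratio, "prev_current": prev_cur,
                "prev_eco2": prev_e, "delta_points": 100.0 * delta,
                "newly_at_risk": newly, "already_deficient": already,
            }

        if nutrient == "folate":
            idx = cw.repro_idx
            w = cw.birth_weights.copy()
            mc, me = m_cur[idx], m_e[idx]
            usable = (mc > 0) & (me > 0) & (w > 0)
            ewr_cur = np.full(len(idx), np.nan)
            ewr_e = np.full(len(idx), np.nan)
            if usable.any():
                ewr_cur[usable] = ntd.exposure_weighted_rr_many(
                    mc[usable], cw.cv * mc[usable], cw.curve
                )
                ewr_e[usable] = ntd.exposure_weighted_rr_many(
                    me[usable], cw.cv * me[usable], cw.curve
                )
            w = np.where(usable, w, 0.0)
            cidx = cw.country_idx[idx]
            n_c = len(cw.countries)
            s_cur = np.bincount(cidx, weights=np.nan_to_num(ewr_cur) * w, minlength=n_c)
            s_e = np.bincount(cidx, weights=np.nan_to_num(ewr_e) * w, minlength=n_c)
            with np.errstate(divide="ignore", invalid="ignore"):
                pif = np.where(s_cur > 0, (s_e - s_cur) / s_cur, 0.0)
            pif_by_country = pif
            for measure in ("deaths", "dalys"):
                cur = burden[measure]
                add = pif * cur
                for name, arr in ((f"attributable_{measure}", add), (f"current_{measure}", cur)):
                    n_rg = len(cw.regions)
                    reg = np.bincount(cw.country_region_idx, weights=arr, minlength=n_rg)
                    for i, r in enumerate(cw.regions):
                        metrics[(r, "folate", name)] = float(reg[i])
                    metrics[("global", "folate", name)] = float(arr.sum())
            if keep_strata:
                per_stratum["ntd"] = {
                    "pif": pif,
                    "attributable_deaths": pif * burden["deaths"],
                    "attributable_dalys": pif * burden["dalys"],
                }

    return metrics, per_stratum


def sample_draw_inputs(cw: CompiledWorld, rng: np.random.Generator):
    """Sample one Monte Carlo draw; fixed draw order.

    Order: rice supply noise, non-rice supply noise (per nutrient, stratum
    blocks), loss factor per nutrient, burden deaths then DALYs per
    country.  Returns None when the draw is inconsistent (any negative
    supply or burden) so the caller can redraw.
    """
    rice = cw.rice + cw.se_rice * rng.standard_normal(cw.rice.shape)
    nonrice = cw.nonrice + cw.se_nonrice * rng.standard_normal(cw.nonrice.shape)
    frac_change = np.array(
        [
            float(p.rvs(1, rng)[0]) if p.omega > 0 else p.xi
            for p in cw.loss_sampler
        ]
    )
    burden = {}
    for measure in ("deaths", "dalys"):
        burden[measure] = np.array(
            [float(p.rvs(1, rng)[0]) if p.omega > 0 else cw.burden_mean[measure][i]
             for i, p in enumerate(cw.burden_sampler[measure])]
        )
    if (rice < 0).any() or (nonrice < 0).any():
        return None
    if any((b < 0).any() for b in burden.values()):
        return None
    return rice, nonrice, np.clip(frac_change, -1.0, 1.0), burden


def run_monte_carlo(cw: CompiledWorld, mc: MonteCarloConfig) -> pd.DataFrame:
    """Point estimates plus middle-95% intervals for every metric.

    The point estimate is the deterministic central run; intervals are
    empirical percentiles over ``mc.n_draws`` resampled pipelines.  A
    fixed seed gives identical output; more than 10% rejected draws is a
    hard error.
    """
    central, _ = compute_draw(cw, cw.rice, cw.nonrice, cw.loss_mean, dict(cw.burden_mean))
    keys = list(central.keys())
    values = np.empty((mc.n_draws, len(keys)))
    root = np.random.SeedSequence(mc.seed)
    children = root.spawn(mc.n_draws)
    rejections = 0
    for d in range(mc.n_draws):
        seq = children[d]
        while True:
            rng = np.random.default_rng(seq)
            drawn = sample_draw_inputs(cw, rng)
            if drawn is not None:
                break
            rejections += 1
            if rejections > 0.10 * mc.n_draws:
                raise RiceshiftError(
                    f"more than 10% of Monte Carlo draws rejected ({rejections})"
                )
            seq = seq.spawn(1)[0]
        m, _ = compute_draw(cw, *drawn)
        values[d] = [m[k] for k in keys]
    if rejections:
        log.warning("rejected and redrew %d inconsistent Monte Carlo draws", rejections)

    rows = []
    for j, (scope, nutrient, metric) in enumerate(keys):
        col = values[:, j]
        col = col[~np.isnan(col)]
        if len(col):
            lo, hi = percentile_interval(col, mc.interval)
        else:
            lo = hi = float("nan")
        rows.append(
            {
                "scope": scope, "nutrient": nutrient, "metric": metric,
                "point": central[(scope, nutrient, metric)],
                "lo95": lo, "hi95": hi, "n_draws": mc.n_draws, "seed": mc.seed,
            }
        )
    return pd.DataFrame(rows)


def run_all(indir: str | Path, outdir: str | Path, config: RunConfig) -> dict:
    """Execute every stage, write all output tables and a run manifest."""
    indir, outdir = Path(indir), Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle = load_world(indir)

    stage = "requirements"
    try:
        ear_table = requirements.build_ear_table(
            bundle["requirements"], bundle["population"], bundle["fertility"],
            bundle["breastfeeding"], bundle["regions"], year=config.year_current,
        )
        tables.write_table(ear_table, outdir / "ear.csv", "ear")

        stage = "fortification"
        if config.fortification and len(bundle["fortification"]):
            added = fortification.stratum_added(
                bundle["fortification"], bundle["vehicle_intake"], bundle["supplies"],
                bundle["population"], year=config.year_current,
            )
        else:
            added = pd.DataFrame(columns=["country", "sex", "age_low", "nutrient", "added"])
        tables.write_table(added, outdir / "added_nutrient.csv", "added_nutrient")

        stage = "scenario"
        cw = compile_world(bundle, config)
        _, per_stratum = compute_draw(
            cw, cw.rice, cw.nonrice, cw.loss_mean, dict(cw.burden_mean), keep_strata=True
        )

        adequacy_rows = []
        scenario_rows = []
        strata = cw.strata
        for nutrient in cw.nutrients:
            ps = per_stratum[nutrient]
            for scen, prev in (("current", ps["prev_current"]), ("eco2", ps["prev_eco2"])):
                adequacy_rows.append(
                    pd.DataFrame(
                        {
                            "country": strata["country"], "sex": strata["sex"],
                            "age_low": strata["age_low"], "nutrient": nutrient,
                            "scenario": scen, "prevalence": prev,
                            "population_at_risk": prev * cw.pop_current,
                        }
                    )
                )
            scenario_rows.append(
                pd.DataFrame(
                    {
                        "country": strata["country"], "sex": strata["sex"],
                        "age_low": strata["age_low"], "nutrient": nutrient,
                        "ratio": ps["ratio"], "prev_current": ps["prev_current"],
                        "prev_eco2": ps["prev_eco2"], "delta_points": ps["delta_points"],
                        "newly_at_risk": ps["newly_at_risk"],
                        "already_deficient": ps["already_deficient"],
                    }
                )
            )
        tables.write_table(pd.concat(adequacy_rows), outdir / "adequacy.csv", "adequacy")
        tables.write_table(pd.concat(scenario_rows), outdir / "scenario.csv", "scenario")

        stage = "ntd_burden"
        pop_by_country = (
            pd.Series(cw.pop_current).groupby(cw.country_idx).sum().reindex(
                range(len(cw.countries))
            ).to_numpy()
        )
        nb = per_stratum["ntd"]
        with np.errstate(divide="ignore", invalid="ignore"):
            burden_out = pd.DataFrame(
                {
                    "country": cw.countries,
                    "pif": nb["pif"],
                    "attributable_deaths": nb["attributable_deaths"],
                    "attributable_dalys": nb["attributable_dalys"],
                    "deaths_rate_per_million": 1e6 * nb["attributable_deaths"] / pop_by_country,
                    "dalys_rate_per_million": 1e6 * nb["attributable_dalys"] / pop_by_country,
                }
            )
        tables.write_table(burden_out, outdir / "burden_out.csv", "burden_out")

        stage = "uncertainty"
        results = run_monte_carlo(cw, config.mc)
        tables.write_results(results, outdir / "results.csv")
    except RiceshiftError as err:
        raise RiceshiftError(f"stage {stage!r} failed: {err}") from err

    import riceshift

    outputs = ["ear.csv", "added_nutrient.csv", "adequacy.csv", "scenario.csv",
               "burden_out.csv", "results.csv"]
    manifest = {
        "config": {
            "cv": config.cv, "degree": config.degree,
            "n_draws": config.mc.n_draws, "seed": config.mc.seed,
            "interval": config.mc.interval, "fortification": config.fortification,
            "year_current": config.year_current, "year_future": config.year_future,
            "nutrients": list(config.nutrients),
        },
        "versions": {
            "riceshift": riceshift.__version__,
            "numpy": np.__version__,
            "pandas": pd.__version__,
        },
        "row_counts": {name: int(len(bundle[name])) for name in INPUT_SCHEMAS},
        "outputs": {
            name: {
                "rows": int(len(pd.read_csv(outdir / name))),
                "sha256": tables.checksum(outdir / name),
            }
            for name in outputs
        },
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
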