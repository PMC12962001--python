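"""End-to-end study workflow: files in, report tables out.

Stages, in order: trait extraction from censuses and temperatures ->
community synchrony -> pooled PCA trait space -> functional indices with
pool-draw SES -> Blomberg's K with permutation p per trait per site ->
trait-evolution model fits with AIC -> MPD/MNTD SES -> richness
rarefaction -> merged-belt reanalysis.  Every output is a tidy CSV plus
a JSON manifest (seed, parameters, versions) sufficient to re-run the
analysis bit-identically.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .funcspace import build_trait_space, fdis, fric, raoq
from .nulls import _summarise
from .phenology import (
    TRAIT_COLUMNS,
    augspurger_synchrony,
    build_trait_table,
    read_census_csv,
    read_site_calendars,
    read_temperature_csv,
)
from .signal import (
    TraitEvolutionModel,
    blomberg_k_many,
    merge_communities,
    phylogenetic_signal,
    pruned_vcv,
    rarefy_signal,
    select_model,
)
from .structure import CommunityMatrix, phylo_ses
from .treeio import Phylogeny

__all__ = ["RunConfig", "PipelineError", "validate_inputs", "run_pipeline"]

#: traits reported in the main signal table; the GDD5-based ones go to a
#: supplementary table (they track the GDD0 ones almost exactly)
MAIN_TRAITS = ["FF_DOY", "FF", "PFP", "PFA", "FSL", "GDD0FF", "GDD0PFP", "GDD0PFA"]
SUPPLEMENTARY_TRAITS = ["GDD5FF", "GDD5PFP", "GDD5PFA"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage '{stage}' failed: {detail}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and parameters of one pipeline run."""

    tree: str
    communities: str
    census: str
    temperatures: dict[str, str]  # site -> csv path
    calendar: str
    output_dir: str
    t_bases: tuple[float, float] = (0.0, 5.0)
    n_null_functional: int = 9999
    n_null_phylo: int = 999
    n_perm_signal: int = 999
    rarefaction_levels: dict[str, list[int]] = field(default_factory=dict)
    n_rarefaction_subsamples: int = 999
    merge_pairs: list[list[str]] = field(default_factory=list)
    n_pca_components: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        base = Path(path).parent
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        for key in ("tree", "communities", "census", "calendar"):
            raw[key] = str((base / raw[key]).resolve())
        raw["temperatures"] = {
            site: str((base / p).resolve()) for site, p in raw["temperatures"].items()
        }
        raw["output_dir"] = str((base / raw["output_dir"]).resolve())
        if "t_bases" in raw:
            raw["t_bases"] = tuple(raw["t_bases"])
        return cls(**raw)

    def to_manifest(self) -> dict:
        out = dict(self.__dict__)
        out["t_bases"] = list(self.t_bases)
        out["version"] = __version__
        return out


def _load_inputs(config: RunConfig):
    tree = Phylogeny.from_file(config.tree)
    communities = CommunityMatrix.from_csv(config.communities)
    censuses = read_census_csv(config.census)
    calendars = read_site_calendars(config.calendar)
    temperatures = {
        site: read_temperature_csv(path, site)
        for site, path in config.temperatures.items()
    }
    return tree, communities, censuses, calendars, temperatures


def validate_inputs(config: RunConfig) -> list[dict]:
    """Cross-check the input bundle; returns a list of issue dicts
    ({'level': 'error'|'warning', 'message': ...}) without raising."""
    issues: list[dict] = []

    def err(msg):
        issues.append({"level": "error", "message": msg})

    def warn(msg):
        issues.append({"level": "warning", "message": msg})

    for key in ("tree", "communities", "census", "calendar"):
        if not Path(getattr(config, key)).exists():
            err(f"missing input file: {getattr(config, key)}")
    for site, path in config.temperatures.items():
        if not Path(path).exists():
            err(f"missing temperature file for {site}: {path}")
    if issues:
        return issues
    tree, communities, censuses, calendars, temperatures = _load_inputs(config)
    tips = set(tree.tip_labels)
    censused = {(c.site_id, c.species_id) for c in censuses}
    for site in communities.sites:
        if site not in calendars:
            err(f"site {site} has no calendar entry")
            continue
        for sp in communities.species_at(site):
            if sp not in tips:
                err(f"community species without a tree tip: {site}/{sp}")
            if (site, sp) not in censused:
                err(f"community species without census data: {site}/{sp}")
    for site, cal in calendars.items():
        if site not in temperatures:
            err(f"site {site} has no temperature series")
            continue
        dates = temperatures[site].samples["timestamp"].dt.date
        if dates.min() > cal.snowmelt_date or dates.max() < cal.season_end:
            err(
                f"temperature coverage for {site} ({dates.min()}..{dates.max()}) "
                f"does not span snowmelt..season end"
            )
    for cs in censuses:
        if not cs.ever_flowers:
            warn(f"species never recorded flowering (will be dropped): "
                 f"{cs.site_id}/{cs.species_id}")
        gaps = pd.Series(cs.records["date"]).diff().dropna().map(lambda d: d.days)
        if len(gaps) and gaps.max() > 2 * gaps.min():
            warn(f"census gap > 2x interval for {cs.site_id}/{cs.species_id}")
    return issues


def _functional_stage(trait_space, traits, communities, n_reps, gen):
    """Observed FRic/FDis/RaoQ per site plus pool-draw SES for each.

    One shared set of occurrence-row draws feeds all three indices.
    """
    all_ids = list(trait_space.occurrence_ids)
    coords = trait_space.coordinates
    rows = []
    for site in communities.sites:
        ids = [(s, sp) for (s, sp) in all_ids if s == site]
        pts = trait_space.rows(ids)
        size = len(ids)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            obs = {"FRic": fric(pts), "FDis": fdis(pts), "RaoQ": raoq(pts)}
            nulls = {k: np.empty(n_reps) for k in obs}
            for r in range(n_reps):
                idx = gen.choice(len(all_ids), size=size, replace=False)
                npts = coords[idx]
                nulls["FRic"][r] = fric(npts)
                nulls["FDis"][r] = fdis(npts)
                nulls["RaoQ"][r] = raoq(npts)
        row = {"site": site, "richness": size}
        for k in ("FRic", "FDis", "RaoQ"):
            res = _summarise(obs[k], nulls[k], None, p_kind="two_tailed")
            row[f"{k}_obs"] = res.observed
            row[f"{k}_SES"] = res.ses
            row[f"{k}_p"] = res.p
        rows.append(row)
    return pd.DataFrame(rows)


def _signal_stage(tree, traits, communities, n_perm, gen):
    full_vcv = tree.vcv_matrix()
    rows = []
    for site in communities.sites:
        site_traits = traits.loc[site]
        species = [s for s in communities.species_at(site) if s in site_traits.index]
        C = pruned_vcv(full_vcv.submatrix(species).values)
        for trait_name in TRAIT_COLUMNS:
            x = site_traits.loc[species, trait_name]
            if x.nunique() <= 1:  # constant trait: signal undefined
                rows.append(
                    {"site": site, "trait": trait_name, "K": np.nan, "p": np.nan,
                     "n_species": len(species), "n_perm": n_perm}
                )
                continue
            res = phylogenetic_signal(
                _as_vcv(C, species), x, trait_name, n_perm=n_perm, rng=gen
            )
            rows.append({"site": site, **res.to_dict()})
    return pd.DataFrame(rows)


def _as_vcv(C, labels):
    from .treeio import DistanceMatrix

    return DistanceMatrix(list(labels), C, kind="covariance")


def _model_stage(tree, traits, communities):
    rows = []
    for site in communities.sites:
        site_traits = traits.loc[site]
        species = [s for s in communities.species_at(site) if s in site_traits.index]
        sub = tree.prune(species)
        for trait_name in TRAIT_COLUMNS:
            x = site_traits.loc[species, trait_name]
            if x.std(ddof=1) == 0:
                continue
            model = TraitEvolutionModel(x, sub)
            fits = model.fit_all()
            best = select_model(fits).model if len(fits) > 1 else fits[0].model
            for f in fits:
                rows.append(
                    {"site": site, "trait": trait_name, **f.to_dict(),
                     "best": f.model == best}
                )
    return pd.DataFrame(rows)


def _structure_stage(tree, communities, n_reps, gen):
    dist = tree.cophenetic_matrix()
    rows = []
    for site in communities.sites:
        species = communities.species_at(site)
        row = {"site": site, "richness": len(species)}
        for metric in ("mpd", "mntd"):
            res = phylo_ses(
                species, tree, metric, n_reps=n_reps, rng=gen, dist=dist
            )
            row[f"{metric.upper()}_obs"] = res.observed
            row[f"{metric.upper()}_SES"] = res.ses
            row[f"{metric.upper()}_p"] = res.p
        rows.append(row)
    return pd.DataFrame(rows)


def _rarefaction_stage(tree, traits, communities, config, gen):
    frames = []
    for site, levels in config.rarefaction_levels.items():
        site_traits = traits.loc[site]
        species = [s for s in communities.species_at(site) if s in site_traits.index]
        for trait_name in MAIN_TRAITS:
            curve = rarefy_signal(
                tree,
                site_traits[trait_name],
                species,
                levels=[lev for lev in levels if lev <= len(species)],
                n_subsamples=config.n_rarefaction_subsamples,
                n_perm=config.n_perm_signal,
                rng=gen,
                trait_name=trait_name,
            )
            df = curve.summary()
            df.insert(0, "trait", trait_name)
            df.insert(0, "site", site)
            frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["site", "trait", "level", "median_K", "prop_significant",
                     "n_subsamples"]
        )
    return pd.concat(frames, ignore_index=True)


def _merge_stage(tree, traits, communities, config, n_perm, gen):
    rows = []
    for pair in config.merge_pairs:
        a, b = pair
        merged = merge_communities(traits.loc[a], traits.loc[b])
        name = f"{a}+{b}"
        species = list(merged.index)
        C = pruned_vcv(tree.vcv_matrix().submatrix(species).values)
        for trait_name in TRAIT_COLUMNS:
            res = phylogenetic_signal(
                _as_vcv(C, species), merged[trait_name], trait_name,
                n_perm=n_perm, rng=gen,
            )
            rows.append({"community": name, "richness": len(species), **res.to_dict()})
    return pd.DataFrame(rows)


def _synchrony_stage(censuses, communities):
    rows = []
    for site in communities.sites:
        site_series = [c for c in censuses if c.site_id == site and c.ever_flowers]
        if len(site_series) < 2:
            continue
        dates = sorted({d for c in site_series for d in c.records["date"]})
        presence = pd.DataFrame(
            {
                c.species_id: [
                    bool(
                        (c.records.loc[c.records["date"] == d, "n_plants"] > 0).any()
                    )
                    for d in dates
                ]
                for c in site_series
            }
        ).T
        per_species, site_mean = augspurger_synchrony(presence)
        for sp, x in per_species.items():
            rows.append({"site": site, "species": sp, "synchrony": x,
                         "site_mean": site_mean})
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; returns the report tables and writes them as CSV."""
    issues = validate_inputs(config)
    blocking = [i for i in issues if i["level"] == "error"]
    if blocking:
        raise PipelineError(
            "validate_inputs", "; ".join(i["message"] for i in blocking)
        )
    gen = np.random.default_rng(config.seed)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    tree, communities, censuses, calendars, temperatures = _load_inputs(config)

    reports: dict[str, pd.DataFrame] = {}

    def stage(name, fn, *args, **kwargs):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return fn(*args, **kwargs)
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError(name, str(exc)) from exc

    traits = stage(
        "traits", build_trait_table, censuses, calendars, temperatures, config.t_bases
    )
    reports["traits"] = traits.reset_index()
    reports["synchrony"] = stage("synchrony", _synchrony_stage, censuses, communities)
    space = stage("trait_space", build_trait_space, traits, config.n_pca_components)
    reports["trait_space"] = space.to_frame().reset_index()
    reports["functional"] = stage(
        "functional", _functional_stage, space, traits, communities,
        config.n_null_functional, gen,
    )
    signal_table = stage(
        "signal", _signal_stage, tree, traits, communities, config.n_perm_signal, gen
    )
    reports["signal"] = signal_table[signal_table["trait"].isin(MAIN_TRAITS)]
    reports["signal_supplementary"] = signal_table[
        signal_table["trait"].isin(SUPPLEMENTARY_TRAITS)
    ]
    reports["model_fits"] = stage("model_fits", _model_stage, tree, traits, communities)
    reports["structure"] = stage(
        "structure", _structure_stage, tree, communities, config.n_null_phylo, gen
    )
    reports["rarefaction"] = stage(
        "rarefaction", _rarefaction_stage, tree, traits, communities, config, gen
    )
    reports["merged"] = stage(
        "merged", _merge_stage, tree, traits, communities, config,
        config.n_perm_signal, gen,
    )

    for name, df in reports.items():
        df.to_csv(outdir / f"{name}.csv", index=False, float_format="%.10g")
    manifest = config.to_manifest()
    manifest["issues"] = issues
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return reports
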