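"""End-to-end orchestration: filter -> costs -> distances -> clustering ->
characterization -> plots, with a machine-readable run report."""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .characterize import backward_stepwise_aic, bivariate_screen, prepare_covariates
from .cluster import agglomerate, cut, pam_medoids, select_solution
from .costs import build_cost_model
from .io import read_cohort
from .model import Cohort, filter_min_observations
from .om import pairwise_distance_matrix
from .simulate import default_config, generate_cohort, load_config, summarize_cohort

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Configuration for a full pipeline run.

    Either ``trajectory_path`` (+ optional ``covariate_path``) points at
    input CSVs, or the synthetic generator is used (``simulate=True``).
    """

    simulate: bool = True
    trajectory_path: str | None = None
    covariate_path: str | None = None
    generator_config: str | None = None  # YAML path; None = packaged defaults
    n_raw: int | None = None
    seed: int = 0
    min_obs: int = 6
    method: str = "complete"  # complete | ward | pam
    k: int | None = None  # None = automatic selection
    k_range: tuple[int, int] = (2, 10)
    min_frac: float = 0.011
    channel_weights: dict = field(default_factory=dict)
    alpha: float = 0.05
    missing_threshold: float = 0.005
    characterize: bool = True
    plots: bool = False
    out_dir: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def match_clusters_to_archetypes(labels: np.ndarray, latent: np.ndarray) -> dict[int, str]:
    """Map each recovered cluster to its majority latent archetype.

    Clusters are processed by decreasing overlap with their majority
    archetype, so when two clusters share a majority the better-matching
    cluster claims it and the other falls back to its next-best archetype.
    """
    labels = np.asarray(labels)
    latent = np.asarray(latent)
    ctab = pd.crosstab(pd.Series(labels), pd.Series(latent))
    mapping: dict[int, str] = {}
    taken: set[str] = set()
    order = ctab.max(axis=1).sort_values(ascending=False).index
    for cl in order:
        row = ctab.loc[cl].sort_values(ascending=False)
        choice = next((a for a in row.index if a not in taken), row.index[0])
        mapping[int(cl)] = choice
        taken.add(choice)
    return mapping


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and return the run report (a JSON-ready dict).

    Stages: load or simulate the cohort; apply the minimum-observations
    filter; build the cost model; compute the multichannel OM distance
    matrix; cluster (with automatic cluster-count selection unless ``k`` is
    fixed); characterize clusters from baseline covariates; optionally
    render plots.  Deterministic given (config, seed).
    """
    t0 = time.time()
    report: dict = {
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
    }

    stage = "load"
    try:
        latent = None
        if config.simulate:
            gen_cfg = (
                load_config(config.generator_config)
                if config.generator_config
                else default_config()
            )
            if config.n_raw:
                from dataclasses import replace

                gen_cfg = replace(gen_cfg, n_raw=config.n_raw)
            cohort, latent = generate_cohort(gen_cfg, seed=config.seed)
        else:
            if not config.trajectory_path:
                raise ValueError("trajectory_path required when simulate=False")
            cohort = read_cohort(config.trajectory_path, config.covariate_path)
        report["n_raw"] = cohort.n

        stage = "filter"
        kept, retained, excluded = filter_min_observations(cohort, config.min_obs)
        report["n_retained"] = kept.n
        report["n_excluded"] = len(excluded)
        if latent is not None:
            id_to_latent = dict(zip(cohort.ids, latent))
            latent = np.array([id_to_latent[i] for i in kept.ids])
        report["summary"] = {
            k: v
            for k, v in summarize_cohort(kept).items()
            if k in ("nonresponse_share", "never_above_none")
        }
        log.info("filter: retained %d of %d", kept.n, cohort.n)

        stage = "distances"
        log.info(
            "defaults in effect: ordinal substitution costs normalised to "
            "max 2 per channel, half-max indel (=1), nonresponse at indel, "
            "incapacity = highest level, death one unit beyond; channel "
            "weights %s; min cluster fraction %s; dummy reference = first "
            "category; missing-category threshold %s",
            config.channel_weights or "all 1", config.min_frac,
            config.missing_threshold,
        )
        cm = build_cost_model(kept.specs, weights=config.channel_weights)
        dm = pairwise_distance_matrix(kept, cm)

        stage = "clustering"
        if config.method == "pam":
            if config.k is None:
                raise ValueError("PAM requires an explicit k")
            sol = pam_medoids(dm, config.k, seed=config.seed)
        else:
            tree = agglomerate(dm, config.method)
            if config.k is not None:
                sol = cut(tree, config.k, dm, method=config.method)
            else:
                lo, hi = config.k_range
                sol = select_solution(
                    tree, dm, range(lo, hi + 1), config.min_frac, method=config.method
                )
        report["clustering"] = {
            "method": config.method,
            "k": sol.k,
            "sizes": sol.sizes.tolist(),
            "asw": sol.asw,
            "asw_curve": {str(k): v for k, v in sol.asw_curve.items()},
            "size_threshold": sol.size_threshold,
            "k_fixed": config.k is not None,
        }
        labels = pd.Series(sol.labels, index=kept.ids, name="cluster")
        if latent is not None:
            mapping = match_clusters_to_archetypes(sol.labels, latent)
            shares = {
                arch: float((sol.labels == cl).mean())
                for cl, arch in mapping.items()
            }
            report["archetype_matching"] = {
                "mapping": {str(k): v for k, v in mapping.items()},
                "recovered_share": shares,
            }

        stage = "characterization"
        if config.characterize and kept.covariates is not None:
            prepared = prepare_covariates(kept.covariates, config.missing_threshold)
            screen, entry = bivariate_screen(
                prepared, labels, alpha=config.alpha
            )
            selected, model, trace = backward_stepwise_aic(entry, prepared, labels)
            report["characterization"] = {
                "n_model": model.n,
                "entry_covariates": entry,
                "selected_covariates": selected,
                "aic_trace": [
                    {"covariates": t["covariates"], "aic": t["aic"], "dropped": t["dropped"]}
                    for t in trace
                ],
                "reference_cluster": model.reference,
                "aic": model.aic,
                "log_likelihood": model.llf,
                "bivariate": screen.assign(df=screen.df.astype(str)).to_dict("records"),
            }
        else:
            model = screen = None

        stage = "outputs"
        if config.out_dir:
            out = Path(config.out_dir)
            out.mkdir(parents=True, exist_ok=True)
            header = (
                f"# caretraj {__version__} seed={config.seed} "
                f"config={report['config_hash']}\n"
            )
            with open(out / "labels.csv", "w", encoding="utf-8") as fh:
                fh.write(header)
                labels.rename_axis("id").to_csv(fh)
            if model is not None:
                with open(out / "odds_ratios.csv", "w", encoding="utf-8") as fh:
                    fh.write(header)
                    model.or_table.to_csv(fh, index=False)
                screen.to_csv(out / "bivariate_tests.csv", index=False)
            if config.plots:
                from .plots import plot_index_and_frequency, plot_state_distribution

                plot_state_distribution(kept, out / "state_distribution.png")
                plot_state_distribution(
                    kept, out / "state_distribution_by_cluster.png", labels=sol.labels
                )
                plot_index_and_frequency(kept, out / "sequences")
            report["runtime_s"] = round(time.time() - t0, 2)
            with open(out / "report.json", "w", encoding="utf-8") as fh:
                json.dump(report, fh, indent=2, default=float)
        report.setdefault("runtime_s", round(time.time() - t0, 2))
    except Exception as exc:
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    return report
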