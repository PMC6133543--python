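"""End-to-end orchestration: KT -> sensitivity -> rates -> shifts.

A single YAML config drives the full analysis on a (tree, trait table)
pair.  Each stage writes a machine-readable artifact into the run
directory:

* ``kt.csv``           per-species KT under the configured protocol;
* ``sensitivity.csv``  one PGLS row per mobile link (coefficient, SE, t,
                       p, r^2, AIC, lambda);
* ``rates.json``       per-link sigma^2 with 95% CIs and equal-vs-free
                       likelihood-ratio tests, joint and pairwise;
* ``shifts/``          per-branch posterior shift probabilities, the
                       strongly-supported-shift table, parameter traces
                       and convergence statistics (optional stage);
* ``run.log``          seed, config echo and stage progress.

All stages are pure functions of (inputs, config, seed); rerunning a
config reproduces the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import LinkageEvoError
from .fourbar import FourBarLinkage, assembly_range, kt_for_protocol
from .pgls import MOBILE_LINKS, sensitivity_scan
from .phylo import Phylogeny, TraitTable, prune_to_overlap, read_newick
from .rates import compare_rates
from .shifts import rjmcmc_shifts, summarize_shifts

__all__ = ["RunConfig", "run_pipeline", "validate_inputs", "compute_kt_table"]

log = logging.getLogger("linkage_evo")


@dataclass
class RunConfig:
    """Configuration for one pipeline run (see package docs for fields)."""

    tree: str
    traits: str
    out_dir: str
    kt_mode: str = "static"          # static | min | min-range | mean | column
    start_angle: float = 30.0
    rotation: float = 9.0
    step: float = 0.1
    response: str = "kt"
    links: tuple[str, ...] = MOBILE_LINKS
    lambda_mode: str | float = "ML"
    measurement_error: bool = False
    run_shifts: bool = False
    shift_trait: str = "kt"
    ngen: int = 200_000
    burnin: float = 0.30
    chains: int = 2
    pp_threshold: float = 0.5
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        if "links" in raw:
            raw["links"] = tuple(raw["links"])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dict(self.__dict__)
        d["links"] = list(self.links)
        return d

    def digest(self) -> str:
        # output location does not affect the analysis, so it is excluded:
        # identical configs produce byte-identical outputs wherever written
        d = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _write_csv(frame: pd.DataFrame, path: Path, config_hash: str, index=True) -> None:
    with open(path, "w", newline="") as fh:
        fh.write(f"# config_hash: {config_hash}\n")
        frame.to_csv(fh, index=index)


def compute_kt_table(
    table: TraitTable,
    mode: str = "static",
    start_angle: float = 30.0,
    rotation: float = 9.0,
    step: float = 0.1,
) -> TraitTable:
    """Add (or keep) a ``kt`` column computed from the four link columns."""
    if mode == "column":
        if "kt" not in table.frame.columns:
            raise LinkageEvoError("kt_mode=column requires a kt column in the table")
        return table
    lengths = table.values(["fixed", "input", "output", "coupler"])
    kts = np.empty(len(table))
    for i, row in enumerate(lengths):
        linkage = FourBarLinkage(*row)
        kts[i] = kt_for_protocol(linkage, mode, start_angle, rotation, step)
    return table.with_column("kt", kts)


def validate_inputs(tree: Phylogeny, table: TraitTable) -> dict:
    """Report-only consistency checks on a (tree, table) pair."""
    issues = []
    tree_set, table_set = set(tree.tip_labels), set(table.species)
    overlap = tree_set & table_set
    if not overlap:
        issues.append({"severity": "fatal", "message": "no shared species labels"})
    elif overlap != tree_set or overlap != table_set:
        issues.append({
            "severity": "info",
            "message": f"{len(tree_set - overlap)} tree-only and "
                       f"{len(table_set - overlap)} table-only species will be pruned",
        })
    if not tree.is_ultrametric():
        issues.append({"severity": "warning", "message": "tree is not ultrametric"})
    na_cols = [c for c in table.trait_columns if table.frame[c].isna().any()]
    if na_cols:
        issues.append({"severity": "warning", "message": f"missing values in {na_cols}"})
    link_cols = {"fixed", "input", "output", "coupler"}
    if link_cols <= set(table.frame.columns):
        for sp, row in table.frame[list(link_cols)].iterrows():
            try:
                assembly_range(FourBarLinkage(
                    row["fixed"], row["input"], row["output"], row["coupler"]))
            except Exception as exc:
                issues.append({
                    "severity": "warning",
                    "message": f"non-closable linkage for {sp}: {exc}",
                })
    return {"n_overlap": len(overlap), "issues": issues}


def run_pipeline(config: RunConfig) -> Path:
    """Run every configured stage; returns the run directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    cfg_hash = config.digest()
    try:
        log.info("linkage-evo %s | config %s | seed %d", __version__, cfg_hash, config.seed)
        log.info("config: %s", json.dumps(config.to_dict(), sort_keys=True))

        stage = "load"
        tree = read_newick(config.tree)
        table = TraitTable.from_csv(config.traits)
        report = validate_inputs(tree, table)
        for issue in report["issues"]:
            log.warning("[validate] %s: %s", issue["severity"], issue["message"])
        tree, table = prune_to_overlap(tree, table)
        log.info("[load] %d species after pruning", tree.n_tips)

        stage = "kt"
        table = compute_kt_table(
            table, config.kt_mode, config.start_angle, config.rotation, config.step
        )
        _write_csv(table.frame[["kt"]], out / "kt.csv", cfg_hash)
        log.info("[kt] protocol=%s", config.kt_mode)

        stage = "sensitivity"
        fits = sensitivity_scan(
            table, tree, response=config.response, links=config.links,
            lam=config.lambda_mode,
        )
        rows = []
        for link in config.links:
            f = fits[link]
            rows.append({
                "Predictor": link,
                "Coeff": f.coef(link),
                "SE": float(f.std_errors[f.names.index(link)]),
                "T": float(f.t_stats[f.names.index(link)]),
                "P": float(f.p_values[f.names.index(link)]),
                "r2": f.r_squared,
                "AIC": f.aic,
                "lambda": f.lambda_ml,
            })
        _write_csv(pd.DataFrame(rows), out / "sensitivity.csv", cfg_hash, index=False)
        log.info("[sensitivity] top link by r2: %s",
                 max(rows, key=lambda r: r["r2"])["Predictor"])

        stage = "rates"
        logged = table.log_transformed(list(config.links))
        me = None
        if config.measurement_error:
            me_cols = [l + TraitTable.ME_SUFFIX for l in config.links]
            if all(c in table.frame.columns for c in me_cols):
                me = np.column_stack([table.me_variance(l) for l in config.links])
            else:
                log.warning("[rates] measurement error requested but columns missing")
        comparison = compare_rates(logged, tree, me=me, columns=list(config.links))
        payload = {"config_hash": cfg_hash, **comparison.to_dict()}
        (out / "rates.json").write_text(json.dumps(payload, indent=2) + "\n")
        log.info("[rates] LRT=%.3f df=%d p=%.3g",
                 comparison.lrt_stat, comparison.df, comparison.p_value)

        if config.run_shifts:
            stage = "shifts"
            shift_dir = out / "shifts"
            shift_dir.mkdir(exist_ok=True)
            y = np.log(table.values([config.shift_trait]).ravel())
            post = rjmcmc_shifts(
                y, tree, n_generations=config.ngen, burnin=config.burnin,
                chains=config.chains, seed=config.seed,
            )
            _write_csv(
                pd.DataFrame({"branch": np.arange(post.n_branches),
                              "pp": post.branch_pp}),
                shift_dir / "branch_pp.csv", cfg_hash, index=False,
            )
            _write_csv(summarize_shifts(post, config.pp_threshold),
                       shift_dir / "regimes.csv", cfg_hash, index=False)
            for c, tr in enumerate(post.traces):
                frame = pd.DataFrame({k: v for k, v in tr.items()})
                _write_csv(frame, shift_dir / f"trace_chain{c}.csv", cfg_hash, index=False)
            (shift_dir / "convergence.json").write_text(
                json.dumps({"gelman_r": post.gelman_r,
                            "n_samples_post_burnin": post.n_samples_post_burnin},
                           indent=2) + "\n")
            log.info("[shifts] %d branches above pp=%.2f",
                     int(np.sum(post.branch_pp > config.pp_threshold)),
                     config.pp_threshold)
        log.info("done")
        return out
    except Exception as exc:
        log.error("[%s] failed: %s", stage, exc)
        raise LinkageEvoError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
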