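"""End-to-end orchestration: coding -> ASR/mapping -> signal -> LTT/gamma ->
SSE fitting -> ranking -> averaging -> reconstruction, with file reports.

The pipeline mirrors the standard analysis sequence for a three-state trait
on a time-calibrated tree.  All randomness flows from the single config
seed; each stage draws from its own spawned substream, so disabling one
stage does not shift another's results.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity, signal as signal_mod
from .coding import TraitTable, encode_binary_pair, gap_code
from .mk import build_rate_matrix, fit_mk, marginal_asr
from .simmap import count_transitions, sample_stochastic_maps
from .simulate import simulate_trait_table, yule_tree
from .sse import (build_model_set, fit_sse, marginal_reconstruction_sse,
                  model_average_rates, rank_models, ranking_frame)
from .tree import TimeTree

__all__ = ["RunConfig", "run_pipeline", "write_report"]

STAGES = ("coding", "asr", "map", "signal", "ltt", "sse")


@dataclass
class RunConfig:
    """Everything one pipeline run needs; round-trips through JSON."""

    tree_path: str = None
    traits_path: str = None
    simulate_tips: int = None       # synthetic mode when paths are absent
    seed: int = 0
    stages: tuple = STAGES
    size_classes: int = 3
    mk_models: tuple = ("ER", "SYM", "ARD")
    mk_constrained: bool = True
    n_maps: int = 100
    mk_starts: int = 5
    n_rand: int = 1000              # K permutations
    anova_sims: int = 10_000
    mccr_total: int = None          # full clade size for the MCCR test
    mccr_reps: int = 1000
    sse_traits: tuple = ("size", "ecotype")
    sse_models: tuple = None        # None = all eight
    sse_starts: int = 25
    sse_rho: tuple = None
    average_threshold: float = 1e-3

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        if path and str(path).endswith((".json",)):
            data = json.loads(text)
        else:
            data = {}
            for line in text.splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                key, _, val = line.partition("=")
                data[key.strip()] = json.loads(val.strip())
        for key in ("stages", "mk_models", "sse_traits", "sse_models", "sse_rho"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    def to_file(self, path) -> None:
        data = asdict(self)
        Path(path).write_text(json.dumps(data, indent=2, default=list) + "\n")


def _stage_seeds(seed: int) -> dict:
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(STAGES) + 1)
    seeds = {name: children[i] for i, name in enumerate(STAGES)}
    seeds["simulate"] = children[-1]
    return seeds


def run_pipeline(config: RunConfig) -> dict:
    """Execute the enabled stages in order; returns a result bundle."""
    cfg = config
    seeds = _stage_seeds(cfg.seed)
    results = {"config": asdict(cfg)}

    # ---- inputs -------------------------------------------------------
    if cfg.tree_path:
        tree = TimeTree.from_path(cfg.tree_path)
        traits = TraitTable.from_csv(cfg.traits_path).join_tree(tree)
    else:
        n = cfg.simulate_tips or 300
        rng = np.random.default_rng(seeds["simulate"])
        tree = yule_tree(n, rng=rng)
        traits = simulate_trait_table(tree, rng=rng)
    results["n_tips"] = tree.n_tips
    results["tree"] = tree
    tl = traits.column("total_length_cm", tree.tip_labels)
    bd = traits.column("body_depth_pct", tree.tip_labels)
    eco = traits.column("ecotype", tree.tip_labels)
    farm = traits.column("farming", tree.tip_labels)

    # ---- coding -------------------------------------------------------
    size_states = None
    if "coding" in cfg.stages:
        coding = gap_code(tl.to_numpy(), cfg.size_classes,
                          labels=list(tl.index))
        size_states = coding.assignment
        results["coding"] = {
            "breakpoints": coding.breakpoints.tolist(),
            "class_sizes": {
                c: sum(1 for v in coding.assignment.values() if v == c)
                for c in coding.class_labels
            },
            "assignment": coding.assignment,
        }
    trait_states = {}
    if size_states is not None:
        trait_states["size"] = ({t: size_states[t] for t in tree.tip_labels},
                                ("S", "M", "L"))
    trait_states["ecotype"] = (eco.to_dict(), ("benthic", "intermediate",
                                               "pelagic"))

    # ---- Mk ASR -------------------------------------------------------
    if "asr" in cfg.stages:
        rng_seed = seeds["asr"].generate_state(1)[0] % (2**31)
        rows = []
        fits = {}
        for tname, (states, alphabet) in trait_states.items():
            for model in cfg.mk_models:
                for constrained in ([False, True] if cfg.mk_constrained
                                    else [False]):
                    if constrained and model == "ER":
                        continue
                    spec = build_rate_matrix(alphabet, model,
                                             constrained=constrained)
                    fit = fit_mk(tree, states, spec, n_starts=cfg.mk_starts,
                                 seed=rng_seed)
                    rows.append({"trait": tname, "model": spec.name,
                                 "free_parameters": fit.n_params,
                                 "lnL": fit.loglik, "AIC": fit.aic,
                                 "AICc": fit.aicc})
                    fits[(tname, spec.name)] = fit
        mk_table = pd.DataFrame(rows)
        results["asr"] = {"table": mk_table, "fits": fits}
        results["asr"]["marginals"] = {
            tname: marginal_asr(tree, trait_states[tname][0],
                                fits[(tname, "ARD+constrained")].spec,
                                fits[(tname, "ARD+constrained")].rates)
            for tname in trait_states
        }

    # ---- stochastic mapping ------------------------------------------
    if "map" in cfg.stages and "asr" in cfg.stages:
        rng_seed = seeds["map"].generate_state(1)[0] % (2**31)
        counts = {}
        for tname in trait_states:
            fit = results["asr"]["fits"][(tname, "ARD+constrained")]
            maps = sample_stochastic_maps(
                tree, trait_states[tname][0], fit.spec, fit.rates,
                n_maps=cfg.n_maps, seed=rng_seed)
            counts[tname] = count_transitions(maps, fit.spec)
        results["map"] = counts

    # ---- signal -------------------------------------------------------
    if "signal" in cfg.stages:
        rng_seed = seeds["signal"].generate_state(1)[0] % (2**31)
        sig_rows = []
        for tname, x in (("total_length", np.log(tl.to_numpy())),
                         ("body_depth", bd.to_numpy())):
            k = signal_mod.blomberg_k(tree, x, n_rand=cfg.n_rand,
                                      seed=rng_seed)
            lam = signal_mod.pagel_lambda_continuous(tree, x)
            sig_rows += [
                {"trait": tname, "statistic": "BlombergK",
                 "estimate": k.estimate, "p_value": k.p_value,
                 "n_rand": cfg.n_rand},
                {"trait": tname, "statistic": "PagelLambda",
                 "estimate": lam.estimate, "p_value": lam.p_value,
                 "n_rand": None},
            ]
        for tname, (states, alphabet) in trait_states.items():
            spec = build_rate_matrix(alphabet, "ER")
            lam_d = signal_mod.pagel_lambda_discrete(
                tree, states, spec, seed=rng_seed)
            sig_rows.append({"trait": tname, "statistic": "PagelLambdaDiscrete",
                             "estimate": lam_d.estimate,
                             "p_value": lam_d.p_value, "n_rand": None})
        anova_rows = []
        for gname, groups in (("ecotype", eco.to_dict()),
                              ("farming", farm.to_dict())):
            for yname, y in (("total_length", np.log(tl.to_numpy())),
                             ("body_depth", bd.to_numpy())):
                try:
                    a = signal_mod.phyl_anova(tree, groups, y,
                                              n_sim=cfg.anova_sims,
                                              seed=rng_seed)
                except ValueError:
                    continue  # degenerate grouping in small simulations
                anova_rows.append({"groups": gname, "response": yname,
                                   "F": a.f_statistic, "p_value": a.p_value,
                                   "n_sim": cfg.anova_sims})
        results["signal"] = {"table": pd.DataFrame(sig_rows),
                             "anova": pd.DataFrame(anova_rows)}

    # ---- LTT / gamma --------------------------------------------------
    if "ltt" in cfg.stages:
        rng_seed = seeds["ltt"].generate_state(1)[0] % (2**31)
        curve = diversity.ltt_curve(tree)
        plain = diversity.mccr_test(tree, n_total=tree.n_tips,
                                    n_reps=cfg.mccr_reps, seed=rng_seed)
        out = {"curve": curve, "gamma": plain.gamma,
               "p_plain": plain.p_value}
        if cfg.mccr_total and cfg.mccr_total > tree.n_tips:
            mccr = diversity.mccr_test(tree, n_total=cfg.mccr_total,
                                       n_reps=cfg.mccr_reps, seed=rng_seed)
            out["p_mccr"] = mccr.p_value
            out["mccr_total"] = cfg.mccr_total
        results["ltt"] = out

    # ---- SSE ----------------------------------------------------------
    if "sse" in cfg.stages:
        rng_seed = seeds["sse"].generate_state(1)[0] % (2**31)
        sse_out = {}
        for tname in cfg.sse_traits:
            if tname not in trait_states:
                continue
            states, _ = trait_states[tname]
            codes = encode_binary_pair(states)
            specs = build_model_set(tname, rho=cfg.sse_rho)
            if cfg.sse_models is not None:
                specs = [s for s in specs if s.name in cfg.sse_models]
            fits = [fit_sse(tree, codes, s, n_starts=cfg.sse_starts,
                            seed=rng_seed + i) for i, s in enumerate(specs)]
            ranked = rank_models(fits)
            recons = {
                f.name: marginal_reconstruction_sse(tree, codes, f.spec,
                                                    f.theta)
                for f in ranked if f.weight > cfg.average_threshold
            }
            averaged = model_average_rates(ranked, recons,
                                           threshold=cfg.average_threshold)
            sse_out[tname] = {"ranking": ranking_frame(ranked),
                              "fits": ranked, "averaged": averaged}
        results["sse"] = sse_out
    return results


# ----------------------------------------------------------------------
# reporting
# ----------------------------------------------------------------------
def _netdiv_newick(tree: TimeTree, values: np.ndarray) -> str:
    """Newick with per-node net-diversification comments."""

    def rec(v):
        if v < tree.n_tips:
            core = tree.labels[v]
        else:
            core = "(" + ",".join(rec(c) for c in tree.children[v]) + ")"
        note = f"[&netdiv={values[v]:.6g}]"
        if tree.parent[v] < 0:
            return core + note
        return f"{core}{note}:{tree.brlen[v]:.10g}"

    return rec(tree.root) + ";"


def write_report(results: dict, out_dir) -> dict:
    """Write the result bundle as CSV/JSON files; returns path map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = {}
    summary = {"n_tips": results.get("n_tips")}

    if "coding" in results:
        cd = results["coding"]
        df = pd.DataFrame(
            [{"species": sp, "size_class": c}
             for sp, c in cd["assignment"].items()]
        )
        df.to_csv(out / "size_classes.csv", index=False)
        written["coding"] = "size_classes.csv"
        summary["coding"] = {"breakpoints": cd["breakpoints"],
                             "class_sizes": cd["class_sizes"]}
    if "asr" in results:
        results["asr"]["table"].to_csv(out / "mk_fits.csv", index=False)
        written["asr"] = "mk_fits.csv"
        summary["asr"] = results["asr"]["table"].to_dict(orient="records")
    if "map" in results:
        for tname, tc in results["map"].items():
            df = tc.to_frame()
            df.to_csv(out / f"transition_counts_{tname}.csv", index=False)
            written[f"map_{tname}"] = f"transition_counts_{tname}.csv"
            summary.setdefault("map", {})[tname] = df.to_dict(orient="records")
    if "signal" in results:
        results["signal"]["table"].to_csv(out / "signal.csv", index=False)
        results["signal"]["anova"].to_csv(out / "anova.csv", index=False)
        written["signal"] = "signal.csv"
        summary["signal"] = results["signal"]["table"].to_dict(orient="records")
        summary["anova"] = results["signal"]["anova"].to_dict(orient="records")
    if "ltt" in results:
        lt = results["ltt"]
        pd.DataFrame(lt["curve"], columns=["time", "lineages"]).to_csv(
            out / "ltt.csv", index=False)
        written["ltt"] = "ltt.csv"
        summary["ltt"] = {k: v for k, v in lt.items() if k != "curve"}
    if "sse" in results:
        for tname, block in results["sse"].items():
            block["ranking"].to_csv(out / f"sse_ranking_{tname}.csv",
                                    index=False)
            block["averaged"].to_csv(out / f"sse_rates_{tname}.csv",
                                     index=False)
            long = block["averaged"].melt(
                id_vars="node", value_vars=["p_01", "p_10", "p_11"],
                var_name="state", value_name="probability")
            long["state"] = long["state"].str.removeprefix("p_")
            long = long.rename(columns={"node": "node_id"})
            long.to_csv(out / f"sse_states_{tname}.csv", index=False)
            written[f"sse_{tname}"] = f"sse_ranking_{tname}.csv"
            if "tree" in results:
                nwk = _netdiv_newick(
                    results["tree"],
                    block["averaged"]["net_diversification"].to_numpy())
                (out / f"sse_netdiv_{tname}.nwk").write_text(nwk + "\n")
            summary.setdefault("sse", {})[tname] = (
                block["ranking"].to_dict(orient="records"))
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, default=_json_default) + "\n")
    written["summary"] = "summary.json"
    return written


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serialisable: {type(o)}")
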