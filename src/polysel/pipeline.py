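"""End-to-end pipeline: simulate/load → summarise → indices → gradients →
decomposition → SCIC → report.

One top-level seed fans out (via ``numpy.random.SeedSequence``) into named
per-stage substreams, so each stage is independently reproducible and two
runs with the same config produce byte-identical machine-readable
summaries.  All numeric outputs are computed by the module functions; the
pipeline only formats and writes them.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .core import (
    compute_male_summaries,
    read_mating_events,
    read_paternity,
    read_rosters,
    summaries_to_frame,
    write_mating_events,
    write_paternity,
    write_rosters,
)
from .decomposition import decompose_variance
from .gradients import (
    adjusted_shares,
    adjusted_shares_frame,
    bateman_multivariate,
    gradient_treatment_difference,
    repetitive_gradient,
)
from .network import build_mating_matrices, randomize_scic
from .opportunity import intervals_overlap, selection_indices
from .simulate import SimConfig, SimDataset, make_paired_treatments

logger = logging.getLogger(__name__)

_STAGES = ("simulate", "bootstrap", "randomization")


@dataclass
class RunConfig:
    out_dir: str
    seed: int = 1
    sim: SimConfig | None = None
    events_path: str | None = None
    paternity_path: str | None = None
    roster_path: str | None = None
    n_boot: int = 10_000
    n_rand: int = 1000
    percent_denominator: str = "var_T"
    save_null_draws: bool = False

    def validate(self) -> None:
        from_files = all(
            p is not None
            for p in (self.events_path, self.paternity_path, self.roster_path)
        )
        if self.sim is None and not from_files:
            raise ValueError(
                "RunConfig needs either a SimConfig or all three input paths"
            )


def _stage_seeds(seed: int) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(_STAGES))
    return {
        name: int(child.generate_state(1)[0] % 2**31)
        for name, child in zip(_STAGES, children)
    }


def _load_datasets(config: RunConfig, sim_seed: int) -> dict[str, SimDataset]:
    if config.sim is not None:
        base = dataclasses.replace(config.sim, seed=sim_seed)
        return make_paired_treatments(base)
    rosters = read_rosters(config.roster_path)
    events = read_mating_events(config.events_path, rosters)
    paternity = read_paternity(config.paternity_path)
    datasets: dict[str, SimDataset] = {}
    for treatment in sorted({r.treatment for r in rosters.values()}):
        sub_rosters = {g: r for g, r in rosters.items() if r.treatment == treatment}
        datasets[treatment] = SimDataset(
            events=[e for e in events if e.group_id in sub_rosters],
            paternity=[p for p in paternity if p.group_id in sub_rosters],
            rosters=sub_rosters,
            truth=None,
        )
    return datasets


def run_pipeline(config: RunConfig) -> dict:
    """Run every stage and write the report bundle into ``config.out_dir``.

    Returns the machine-readable summary (also written as
    ``summary.json``).  Any stage failure propagates with the stage name
    prepended.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(config.seed)
    log_lines = [f"polysel {__version__}", f"seed {config.seed}"]
    log_lines += [f"seed[{k}] {v}" for k, v in seeds.items()]

    summary: dict = {"version": __version__, "seed": config.seed, "treatments": {}}
    stage = "load"
    try:
        datasets = _load_datasets(config, seeds["simulate"])
        all_summaries = []
        indices_rows = []
        decomp_rows = []
        scic_rows = []
        grad_rows = []
        for k, (treatment, ds) in enumerate(sorted(datasets.items())):
            stage = f"summarise[{treatment}]"
            write_mating_events(ds.events, out / f"events_{_slug(treatment)}.csv")
            write_paternity(ds.paternity, out / f"paternity_{_slug(treatment)}.csv")
            write_rosters(ds.rosters, out / f"roster_{_slug(treatment)}.csv")
            summaries = compute_male_summaries(ds.events, ds.paternity, ds.rosters)
            sdf = summaries_to_frame(summaries)
            all_summaries.append(sdf)

            stage = f"indices[{treatment}]"
            idx = selection_indices(
                sdf, n_boot=config.n_boot, seed=seeds["bootstrap"] + 10 * k
            )
            idx.insert(0, "treatment", treatment)
            indices_rows.append(idx)

            stage = f"gradients[{treatment}]"
            # vial fecundity can be exactly collinear with N when every
            # focal mates every female; drop it (not the components) then
            try:
                gset = bateman_multivariate(sdf)
                grad_covariates = "group_fecundity+replicate_id"
            except ValueError as err:
                if "collinear" not in str(err) and "saturated" not in str(err):
                    raise
                gset = bateman_multivariate(sdf, covariates=("replicate_id",))
                grad_covariates = "replicate_id"
                logger.warning(
                    "%s: vial fecundity collinear with components; "
                    "gradients fitted with replicate only", treatment
                )
            for std, table in (("mean", gset.multi_mean), ("var", gset.multi_var)):
                t = table.copy()
                t.insert(0, "treatment", treatment)
                t.insert(1, "standardisation", std)
                grad_rows.append(t)
            rep = repetitive_gradient(sdf)
            rep = rep.copy()
            rep.insert(0, "treatment", treatment)
            rep.insert(1, "standardisation", "mean-P")
            grad_rows.append(rep)
            summary["treatments"][treatment] = {
                "n_males": int(len(sdf)),
                "gradient_covariates": grad_covariates,
                "beta_M_multi": gset.beta_M_multi,
                "beta_P_multi": gset.beta_P_multi,
                "beta_N_multi": gset.beta_N_multi,
                "smax_pre_multi": gset.smax_pre_multi,
                "smax_post_multi": gset.smax_post_multi,
                "jones_pre": gset.jones_pre,
                "jones_post": gset.jones_post,
            }

            stage = f"decomposition[{treatment}]"
            dec = decompose_variance(sdf, config.percent_denominator)
            frame = dec.as_frame()
            frame.insert(0, "treatment", treatment)
            decomp_rows.append(frame)
            summary["treatments"][treatment]["var_T"] = dec.var_T
            summary["treatments"][treatment]["D"] = dec.D
            summary["treatments"][treatment]["percent_var_M"] = dec.percents()["var_M"]
            summary["treatments"][treatment]["percent_var_P"] = dec.percents()["var_P"]

            stage = f"scic[{treatment}]"
            matrices = build_mating_matrices(ds.events, ds.rosters)
            res = randomize_scic(
                matrices, n_rand=config.n_rand, seed=seeds["randomization"] + 10 * k
            )
            scic_rows.append(
                {
                    "treatment": treatment,
                    "observed_scic": res.observed,
                    "null_mean": float(np.nanmean(res.null_values)),
                    "null_lo": float(np.nanpercentile(res.null_values, 2.5)),
                    "null_hi": float(np.nanpercentile(res.null_values, 97.5)),
                    "p_lower": res.p_lower,
                    "p_upper": res.p_upper,
                    "p_two_sided": res.p_two_sided,
                    "n_randomisations": res.n_randomisations,
                    "n_margin_unique_groups": len(res.unique_groups),
                }
            )
            summary["treatments"][treatment]["scic"] = res.observed
            summary["treatments"][treatment]["scic_p_lower"] = res.p_lower
            if config.save_null_draws:
                pd.DataFrame({"scic_null": res.null_values}).to_csv(
                    out / f"scic_null_{_slug(treatment)}.csv", index=False
                )

            stage = f"adjusted_shares[{treatment}]"
            adj = adjusted_shares_frame(
                adjusted_shares(ds.events, ds.paternity, ds.rosters)
            )
            adj.to_csv(out / f"adjusted_shares_{_slug(treatment)}.csv", index=False)

        stage = "cross-treatment"
        pooled = pd.concat(all_summaries, ignore_index=True)
        pooled.to_csv(out / "summaries.csv", index=False)
        indices = pd.concat(indices_rows, ignore_index=True)
        indices.to_csv(out / "indices.csv", index=False)
        pd.concat(grad_rows, ignore_index=True).to_csv(
            out / "gradients.csv", index=False
        )
        pd.concat(decomp_rows, ignore_index=True).to_csv(
            out / "decomposition.csv", index=False
        )
        pd.DataFrame(scic_rows).to_csv(out / "scic.csv", index=False)

        if len(datasets) == 2:
            diff = gradient_treatment_difference(
                pooled, predictor="repetitive_rate", response="P",
                covariates=("replicate_id",), standardise_predictor="none",
            )
            summary["repetitive_gradient_difference"] = {
                k: (v if isinstance(v, str) else float(v)) for k, v in diff.items()
            }
            for index_name in ("I", "I_S", "I_P"):
                rows = indices[indices["index"] == index_name]
                (a, b) = (rows.iloc[0], rows.iloc[1])
                summary[f"{index_name}_intervals_overlap"] = bool(
                    intervals_overlap((a.lower, a.upper), (b.lower, b.upper))
                )
        for treatment, idx in zip(sorted(datasets), indices_rows):
            for _, row in idx.iterrows():
                summary["treatments"][treatment][row["index"]] = {
                    "point": float(row["point"]),
                    "lower": float(row["lower"]),
                    "upper": float(row["upper"]),
                }
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    stage = "report"
    (out / "summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True, allow_nan=True) + "\n"
    )
    config_echo = dataclasses.asdict(config)
    (out / "run_config.json").write_text(
        json.dumps(config_echo, indent=2, sort_keys=True) + "\n"
    )
    (out / "run.log").write_text("\n".join(log_lines) + "\n")
    _write_text_summary(summary, out / "summary.txt")
    return summary


def _slug(treatment: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in treatment).strip("_").lower()


def _write_text_summary(summary: dict, path: Path) -> None:
    lines = [f"polysel run (seed {summary['seed']})", ""]
    for treatment, vals in sorted(summary["treatments"].items()):
        lines.append(f"[{treatment}] n={vals['n_males']}")
        for index_name in ("I", "I_S", "I_P"):
            v = vals[index_name]
            lines.append(
                f"  {index_name:<4} = {v['point']:.3f} "
                f"(95% CI {v['lower']:.3f}, {v['upper']:.3f})"
            )
        lines.append(
            f"  multivariate gradients: M={vals['beta_M_multi']:.3f} "
            f"P={vals['beta_P_multi']:.3f} N={vals['beta_N_multi']:.3f}"
        )
        lines.append(
            f"  s'max pre={vals['smax_pre_multi']:.3f} "
            f"post={vals['smax_post_multi']:.3f}"
        )
        lines.append(
            f"  var(T)={vals['var_T']:.3f}  D={vals['D']:.3f}  "
            f"%var_M={vals['percent_var_M']:.1f}  %var_P={vals['percent_var_P']:.1f}"
        )
        lines.append(
            f"  SCIC={vals['scic']:.3f} (p_lower={vals['scic_p_lower']:.3f})"
        )
        lines.append("")
    path.write_text("\n".join(lines))
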