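"""End-to-end pipeline: Kano → psychometrics → AHP → TRIZ → TOPSIS.

The TRIZ stage is advisory: it annotates the report with resolved
conflicts but never alters weights or rankings.  Reports are deterministic
— identical configuration and seed give byte-identical files.  Stage
functions are the same code paths the CLI subcommands use, so standalone
and pipeline runs agree to machine precision.
"""

from __future__ import annotations

import dataclasses
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import ahp, datasets, kano, psychometrics, topsis, triz
from .errors import IntegrityError, ReqrankError
from .survey_io import (
    RunConfig,
    read_item_matrix,
    read_kano_responses,
    read_pairwise_matrix,
    read_scores,
    write_report,
)

logger = logging.getLogger("reqrank.pipeline")


@dataclass
class PipelineResult:
    stages: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)
    seed: int = 0
    timings: dict = field(default_factory=dict)
    divergences: list = field(default_factory=list)

    def report_payload(self) -> dict:
        payload = {"config": self.config, "seed": self.seed, **self.stages}
        if self.divergences:
            payload["divergences"] = self.divergences
        return payload


# ---------------------------------------------------------------------------
# Stage functions (shared by pipeline and CLI subcommands)
# ---------------------------------------------------------------------------


def kano_stage(
    responses, tie_break: Sequence[str] = kano.DEFAULT_TIE_BREAK
) -> tuple[dict, dict[str, list[str]], list[str]]:
    """Classify, tabulate and assign demand types for one response table."""
    dists = kano.tabulate(responses)
    assignments = [kano.assign_category(d, tie_break) for d in dists]
    groups, excluded = kano.category_sets(assignments)
    section = {
        "distributions": {
            d.indicator_id: {
                "a": d.a,
                "o": d.o,
                "m": d.m,
                "i": d.i,
                "r": d.r,
                "q": d.q,
                "n": d.n_respondents,
                "better": d.better,
                "worse": d.worse,
            }
            for d in dists
        },
        "assignments": {a.indicator_id: a.category for a in assignments},
        "tie_broken": [a.indicator_id for a in assignments if a.tie_broken],
        "category_sets": groups,
        "excluded_indifferent": excluded,
    }
    return section, groups, excluded


def reliability_stage(items) -> dict:
    report = psychometrics.battery(items)
    return {
        "alpha": report.alpha,
        "kmo_overall": report.kmo_overall,
        "msa": report.msa,
        "bartlett_chi2": report.bartlett_chi2,
        "bartlett_df": report.bartlett_df,
        "bartlett_p": report.bartlett_p,
    }


def ahp_stage(
    criterion: ahp.PairwiseMatrix,
    locals_: Mapping[str, ahp.PairwiseMatrix],
    method: str = "eigenvector",
    reciprocity: str = "repair_upper",
) -> tuple[dict, ahp.Hierarchy]:
    crit_res = ahp.priority_weights(criterion, method, reciprocity=reciprocity)
    local_res = {
        cat: ahp.priority_weights(m, method, reciprocity=reciprocity)
        for cat, m in locals_.items()
    }
    hierarchy = ahp.synthesize_global(crit_res, local_res)

    def _res_dict(r: ahp.WeightResult) -> dict:
        return {
            "weights": r.as_dict(),
            "lambda_max": r.lambda_max,
            "ci": r.ci,
            "cr": r.cr,
            "ri": r.ri_used,
            "method": r.method,
        }

    section = {
        "criterion": _res_dict(crit_res),
        "local": {cat: _res_dict(r) for cat, r in local_res.items()},
        "global_weights": hierarchy.global_weights,
        "ranking": list(hierarchy.ranking),
    }
    return section, hierarchy


def triz_stage(cases, matrix) -> dict:
    resolved = [triz.resolve(c, matrix) for c in cases]
    table = triz.report_conflicts(resolved)
    return {
        "conflicts": table.to_dict(orient="records"),
        "n_physical": int((table["conflict_type"] == "physical").sum()),
        "n_technical": int((table["conflict_type"] == "technical").sum()),
    }


def topsis_stage(
    matrix: topsis.EvaluationMatrix,
    weights: Mapping[str, float],
    directions: Mapping[str, str] | None = None,
) -> tuple[dict, topsis.TopsisResult]:
    result = topsis.evaluate(matrix, weights, directions)
    section = {
        "weights_used": {i: float(weights[i]) for i in matrix.indicators},
        "s_plus": dict(zip(result.alternatives, map(float, result.s_plus))),
        "s_minus": dict(zip(result.alternatives, map(float, result.s_minus))),
        "closeness": result.closeness_by_alternative(),
        "ranking": list(result.ranking),
        "degenerate": list(result.degenerate),
    }
    return section, result


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------


def run_pipeline(config: RunConfig, write: bool = True) -> PipelineResult:
    """Run all configured stages from files named in the configuration.

    Requires at least the Kano responses, the criterion matrix and one
    local matrix per non-empty category; psychometrics, TRIZ and TOPSIS run
    only when their inputs are configured.
    """
    config.validate_paths()
    result = PipelineResult(config=_echo(config), seed=config.seed)

    def timed(name, fn, *args, **kwargs):
        t0 = time.perf_counter()
        out = fn(*args, **kwargs)
        result.timings[name] = time.perf_counter() - t0
        logger.info("stage %s finished in %.3fs", name, result.timings[name])
        return out

    groups = None
    if config.kano_responses:
        responses = read_kano_responses(config.kano_responses)
        section, groups, _ = timed(
            "kano", kano_stage, responses, tuple(config.tie_break)
        )
        result.stages["kano"] = section

    if config.item_matrix:
        items = read_item_matrix(config.item_matrix)
        result.stages["reliability"] = timed("reliability", reliability_stage, items)

    hierarchy = None
    if config.criterion_matrix:
        criterion = read_pairwise_matrix(config.criterion_matrix)
        locals_ = {
            cat: read_pairwise_matrix(path) for cat, path in config.local_matrices.items()
        }
        if groups is not None:
            _check_groups(groups, locals_)
        section, hierarchy = timed(
            "ahp", ahp_stage, criterion, locals_, config.ahp_method, config.reciprocity
        )
        result.stages["ahp"] = section

    if config.conflicts and config.contradiction_matrix:
        cases = triz.read_conflicts(config.conflicts)
        params = (
            triz.load_parameters(config.triz_parameters) if config.triz_parameters else None
        )
        matrix = triz.load_matrix(config.contradiction_matrix, parameters=params)
        result.stages["triz"] = timed("triz", triz_stage, cases, matrix)

    if config.scores:
        if hierarchy is None:
            raise IntegrityError("TOPSIS needs the AHP stage for its weight vector")
        scores = read_scores(config.scores)
        matrix = topsis.aggregate_scores(scores)
        missing = [i for i in matrix.indicators if i not in hierarchy.global_weights]
        if missing:
            raise IntegrityError(f"no global weight for scored indicator(s) {missing}")
        section, _ = timed(
            "topsis",
            topsis_stage,
            matrix,
            hierarchy.global_weights,
            config.directions or None,
        )
        result.stages["topsis"] = section

    if write:
        write_report(result.report_payload(), config.output_dir, precision=config.precision)
    return result


def _echo(config: RunConfig) -> dict:
    raw = dataclasses.asdict(config)
    raw["tie_break"] = list(config.tie_break)
    return raw


def _check_groups(groups, locals_) -> None:
    for cat, matrix in locals_.items():
        expected = set(groups.get(cat, ()))
        got = set(matrix.items)
        if expected and expected != got:
            raise IntegrityError(
                f"local matrix for {cat!r} covers {sorted(got)}, "
                f"but the Kano stage assigned {sorted(expected)}"
            )


# ---------------------------------------------------------------------------
# Bundled case study
# ---------------------------------------------------------------------------


def run_case_study(out_dir: str | Path | None = None, precision: int = 6) -> PipelineResult:
    """Recompute every stage on the bundled case-study tables.

    Published aggregates are the inputs (raw respondent-level data was
    never released); each stage is recomputed by the package's own rules
    and every known disagreement with the published downstream numbers is
    written to the divergence log instead of being reproduced.
    """
    result = PipelineResult(config={"source": "bundled case study"}, seed=0)

    summary = datasets.sample_accounting_summary()
    result.stages["sample"] = summary

    # Kano: argmax on the renormalized published rows.
    dists = datasets.kano_distributions()
    assignments = [kano.assign_category(d) for d in dists]
    computed = {a.indicator_id: a.category for a in assignments}
    reported = datasets.reported_kano_categories()
    for ind, cat in sorted(reported.items()):
        if computed[ind] != cat:
            result.divergences.append(
                {
                    "stage": "kano",
                    "where": f"published demand-type classification ({ind})",
                    "reported": cat,
                    "computed": computed[ind],
                    "note": "max-frequency rule on the renormalized published row",
                }
            )
    bw = {d.indicator_id: (d.better, d.worse) for d in dists}
    kt = datasets.kano_table()
    for r in kt.itertuples(index=False):
        b, w = bw[r.indicator_id]
        if abs(b * 100 - r.reported_better_pct) > 1.0 or abs(w * 100 - r.reported_worse_pct) > 1.0:
            result.divergences.append(
                {
                    "stage": "kano",
                    "where": f"published Better–Worse values ({r.indicator_id})",
                    "reported": [r.reported_better_pct, r.reported_worse_pct],
                    "computed": [round(b * 100, 2), round(w * 100, 2)],
                    "note": "standard coefficients on the renormalized row",
                }
            )
    groups, excluded = kano.category_sets(assignments)
    result.stages["kano"] = {
        "assignments": computed,
        "category_sets": groups,
        "excluded_indifferent": excluded,
        "better_worse": {k: [v[0], v[1]] for k, v in bw.items()},
    }

    # AHP: repair the printed matrices, then weight and synthesize.
    section, hierarchy = ahp_stage(
        datasets.criterion_matrix(), datasets.local_matrices(), "eigenvector", "repair_upper"
    )
    result.stages["ahp"] = section
    reported_w = datasets.reported_weights()
    for r in reported_w.itertuples(index=False):
        ind = r.indicator
        if ind in hierarchy.global_weights:
            got = hierarchy.global_weights[ind]
            if abs(got - r.combined_weight) > 0.02:
                result.divergences.append(
                    {
                        "stage": "ahp",
                        "where": f"published combined weight ({ind})",
                        "reported": float(r.combined_weight),
                        "computed": round(got, 4),
                        "note": "published column is not the product of its layer weights "
                        "and sums to 2.268",
                    }
                )

    # TRIZ (advisory).
    result.stages["triz"] = triz_stage(datasets.conflicts(), datasets.contradiction_matrix())

    # TOPSIS on the published evaluation matrix with the renormalized
    # published weight vector (the hierarchy above covers 16 indicators,
    # the evaluation matrix a different 15-indicator set — see divergences).
    weights = datasets.reported_weight_vector()
    section, tres = topsis_stage(datasets.evaluation_matrix(), weights)
    result.stages["topsis"] = section
    published_closeness = {"design_scheme": 0.894, "evaluation_sample": 0.167}
    for alt, rep in published_closeness.items():
        got = float(tres.closeness_by_alternative()[alt])
        if abs(got - rep) > 0.005:
            result.divergences.append(
                {
                    "stage": "topsis",
                    "where": f"published relative closeness ({alt})",
                    "reported": rep,
                    "computed": round(got, 4),
                    "note": "published pair violates the two-alternative identity "
                    "C1 + C2 = 1",
                }
            )

    if out_dir is not None:
        write_report(result.report_payload(), out_dir, precision=precision)
    return result
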