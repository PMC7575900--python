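"""Configuration-driven orchestration of the full MR workflow.

``run_pipeline`` executes, in order: optional simulation (or file input),
optional per-exposure meta-analysis, MAF filtering of the outcome,
linear-scale to log-odds conversion for binary outcomes, per-exposure
instrument selection (significance filter + LD clumping, with optional
enrichment or explicit SNP extraction), harmonisation, the univariable
estimators with heterogeneity/pleiotropy diagnostics and funnel data, and —
when at least two exposures are configured — multivariable MR with
conditional instrument-strength statistics.

Outputs are written to a results directory:

* ``results_univariable.tsv`` — method x exposure causal estimates (OR, CI, p)
* ``results_mvmr.tsv``        — direct-effect estimates per exposure
* ``diagnostics.json``        — Q statistics, Egger intercepts, F statistics
* ``funnel.tsv``              — per-SNP ratio/precision coordinates
* ``harmonised_<label>.tsv``, ``instruments_<label>.tsv`` — intermediates
* ``run.log``                 — package/library versions, config echo, seed

Given the same config and seed the directory is byte-identical across runs
(no timestamps are written).  Every random draw flows from the single
mandatory ``seed`` key.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .errors import MRKitError, ParameterError
from .harmonise import HarmonisedSet, harmonise
from .instruments import LDMatrix, clump, enrich_instruments, extract_snps, select_significant
from .meta import meta_fixed
from .mr_multi import build_mvmr_input, conditional_f, mvmr_egger, mvmr_ivw
from .mr_uni import all_univariable, funnel_data
from .sumstats import SumStatTable, filter_maf, read_sumstats, table_lmm_to_logor, write_sumstats
from .synthetic import SimScenario, simulate_two_sample

logger = logging.getLogger(__name__)


class StageError(MRKitError):
    """An error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage '{stage}' failed: {cause}")
        self.stage = stage
        self.cause = cause


DEFAULT_THRESHOLDS = {
    "p_significant": 5e-8,
    "clump_r2": 0.001,
    "clump_window_kb": 10_000,
    "maf_min": None,           # e.g. 0.1 for rare-case binary outcomes
    "bonferroni_n_tests": None,
    "palindrome_policy": "infer",
    "eaf_tolerance": 0.08,
}


def load_config(path) -> dict:
    import yaml

    with open(path) as fh:
        return yaml.safe_load(fh)


def read_harmonised(path, exposure_label="exposure", outcome_label="outcome") -> HarmonisedSet:
    """Rebuild a :class:`HarmonisedSet` from its written TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"snp_id": str, "chrom": str})
    if len(df) == 0:
        raise ParameterError(f"{path}: empty harmonised file")
    actions = pd.DataFrame({"snp_id": df["snp_id"], "action": "aligned"})
    return HarmonisedSet(exposure_label, outcome_label, df, actions)


def _results_frame(rows: list[dict]) -> pd.DataFrame:
    cols = ["exposure", "method", "or", "or_ci_low", "or_ci_high",
            "beta", "se", "ci_low", "ci_high", "pval", "n_snps"]
    return pd.DataFrame(rows, columns=cols)


def run_pipeline(config: dict, out_dir=None) -> dict:
    """Execute the configured workflow; returns a report summary dict."""
    if "seed" not in config:
        raise ParameterError("config must set an explicit integer 'seed'")
    seed = int(config["seed"])
    thresholds = {**DEFAULT_THRESHOLDS, **(config.get("thresholds") or {})}
    n_boot = int(config.get("n_boot", 1000))
    phi = float(config.get("phi", 1.0))
    variance_model = config.get("variance_model", "multiplicative_re")
    out = Path(out_dir or config.get("out_dir", "mr_results"))
    out.mkdir(parents=True, exist_ok=True)
    incomplete = out / "INCOMPLETE"
    incomplete.write_text("pipeline running\n")

    report: dict = {"seed": seed, "stages": []}
    try:
        exposures, outcome, ld = _stage_inputs(config, seed, out, report)
        outcome = _stage_outcome_prep(outcome, thresholds, report)
        instruments = _stage_instruments(exposures, outcome, ld, thresholds, config, out, report)
        uni_rows, funnel_frames, diagnostics = _stage_univariable(
            instruments, outcome, thresholds, n_boot, phi, variance_model, seed, out, report
        )
        mvmr_rows = _stage_mvmr(
            instruments, exposures, outcome, ld, thresholds, diagnostics, report
        )
    except StageError:
        raise
    except Exception as exc:  # pragma: no cover - safety net
        raise StageError("pipeline", exc) from exc

    _results_frame(uni_rows).to_csv(
        out / "results_univariable.tsv", sep="\t", index=False, float_format="%.10g"
    )
    _results_frame(mvmr_rows).to_csv(
        out / "results_mvmr.tsv", sep="\t", index=False, float_format="%.10g"
    )
    if funnel_frames:
        pd.concat(funnel_frames, ignore_index=True).to_csv(
            out / "funnel.tsv", sep="\t", index=False, float_format="%.10g"
        )
    with open(out / "diagnostics.json", "w") as fh:
        json.dump(diagnostics, fh, indent=2, sort_keys=True)
        fh.write("\n")
    _write_run_log(out, config, seed)
    incomplete.unlink()
    report["diagnostics"] = diagnostics
    report["out_dir"] = str(out)
    return report


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def _stage(report: dict, name: str):
    report["stages"].append(name)


def _stage_inputs(config, seed, out, report):
    _stage(report, "inputs")
    try:
        if "scenario" in config:
            sc = dict(config["scenario"])
            sc["seed"] = seed
            scenario = SimScenario.from_dict(sc)
            exposures, outcome, ld, _truth = simulate_two_sample(scenario)
            for t in exposures:
                write_sumstats(t, out / f"simulated_{t.trait_label}.tsv")
            write_sumstats(outcome, out / "simulated_outcome.tsv")
            ld.write(out / "simulated_ld.tsv")
            return exposures, outcome, ld
        exposures = []
        for spec in config["exposures"]:
            paths = spec.get("paths") or [spec["path"]]
            tables = [
                read_sumstats(
                    p, trait_label=spec["label"],
                    trait_type=spec.get("trait_type", "quantitative"),
                    column_map=spec.get("column_map"),
                )
                for p in paths
            ]
            if len(tables) > 1:
                exposures.append(meta_fixed(tables, trait_label=spec["label"]))
                _stage(report, f"meta[{spec['label']}]")
            else:
                exposures.append(tables[0])
        ospec = config["outcome"]
        outcome = read_sumstats(
            ospec["path"], trait_label=ospec.get("label", "outcome"),
            trait_type=ospec.get("trait_type", "binary-logor"),
            column_map=ospec.get("column_map"),
        )
        ld = LDMatrix.read(config["ld"]) if "ld" in config else None
        return exposures, outcome, ld
    except StageError:
        raise
    except Exception as exc:
        raise StageError("inputs", exc) from exc


def _stage_outcome_prep(outcome, thresholds, report):
    _stage(report, "outcome-prep")
    try:
        if thresholds["maf_min"] is not None:
            outcome = filter_maf(outcome, float(thresholds["maf_min"]))
        if outcome.trait_type == "binary-lmm":
            outcome = table_lmm_to_logor(outcome)
        return outcome
    except Exception as exc:
        raise StageError("outcome-prep", exc) from exc


def _stage_instruments(exposures, outcome, ld, thresholds, config, out, report):
    _stage(report, "instruments")
    try:
        selected = {}
        for t in exposures:
            sig = select_significant(t, float(thresholds["p_significant"]))
            if ld is not None:
                sig = clump(
                    sig, ld,
                    r2_threshold=float(thresholds["clump_r2"]),
                    window_kb=int(thresholds["clump_window_kb"]),
                )
            selected[t.trait_label] = sig
        enrich = config.get("enrich")
        if enrich:
            target = enrich["target"]
            source = enrich["candidates_from"]
            n_tests = int(enrich.get("n_tests") or len(selected[source]))
            target_table = next(t for t in exposures if t.trait_label == target)
            selected[target] = enrich_instruments(
                selected[target], selected[source], target_table, n_tests, ld,
                r2_threshold=float(thresholds["clump_r2"]),
                window_kb=int(thresholds["clump_window_kb"]),
            )
            _stage(report, f"enrich[{target}]")
        extract = config.get("extract_snps")
        if extract:
            label = extract["exposure"]
            subset, missing = extract_snps(selected[label], extract["snp_ids"])
            if ld is not None:
                subset = clump(
                    subset, ld,
                    r2_threshold=float(thresholds["clump_r2"]),
                    window_kb=int(thresholds["clump_window_kb"]),
                )
            selected[label] = subset
            _stage(report, f"extract[{label}] missing={len(missing)}")
        for label, table in selected.items():
            write_sumstats(table, out / f"instruments_{label}.tsv")
        return selected
    except StageError:
        raise
    except Exception as exc:
        raise StageError("instruments", exc) from exc


def _stage_univariable(instruments, outcome, thresholds, n_boot, phi,
                       variance_model, seed, out, report):
    _stage(report, "univariable-mr")
    try:
        rows, funnel_frames = [], []
        diagnostics: dict = {"univariable": {}, "mvmr": {}}
        for label, table in instruments.items():
            if len(table) == 0:
                diagnostics["univariable"][label] = {"n_snps": 0, "note": "no instruments"}
                continue
            h = harmonise(
                table, outcome,
                palindrome_policy=thresholds["palindrome_policy"],
                eaf_tolerance=float(thresholds["eaf_tolerance"]),
            )
            h.write(out / f"harmonised_{label}.tsv")
            results, diag = all_univariable(
                h, n_boot=n_boot, seed=seed, phi=phi, variance_model=variance_model
            )
            diagnostics["univariable"][label] = diag
            for r in results:
                rows.append({"exposure": label, **r.to_dict()})
            fd = funnel_data(h, results)
            fd.insert(0, "exposure", label)
            funnel_frames.append(fd)
        return rows, funnel_frames, diagnostics
    except Exception as exc:
        raise StageError("univariable-mr", exc) from exc


def _stage_mvmr(instruments, exposures, outcome, ld, thresholds, diagnostics, report):
    if len(exposures) < 2:
        _stage(report, "mvmr-skipped (single exposure)")
        logger.info("MVMR skipped: only one exposure configured")
        return []
    _stage(report, "mvmr")
    try:
        union_ids: list[str] = []
        for table in instruments.values():
            union_ids.extend(s for s in table.snp_ids if s not in union_ids)
        first = exposures[0]
        rows = []
        pool = {}
        for t in exposures:
            for row in t.df.itertuples(index=False):
                pool.setdefault(row.snp_id, (t, row))
        union_rows = [pool[s][0].df[pool[s][0].df["snp_id"] == s] for s in union_ids if s in pool]
        union_df = pd.concat(union_rows, ignore_index=True) if union_rows else first.df.iloc[:0]
        union = SumStatTable(first.trait_label, first.trait_type, union_df)
        x = build_mvmr_input(
            union, exposures, outcome, ld,
            r2_threshold=float(thresholds["clump_r2"]),
            window_kb=int(thresholds["clump_window_kb"]),
            palindrome_policy=thresholds["palindrome_policy"],
            eaf_tolerance=float(thresholds["eaf_tolerance"]),
        )
        ivw_res = mvmr_ivw(x)
        egger_res, het = mvmr_egger(x)
        for r in ivw_res + egger_res:
            label = r.method.split("[", 1)[1].rstrip("]")
            method = r.method.split("[", 1)[0]
            rows.append({"exposure": label, **{**r.to_dict(), "method": method}})
        diagnostics["mvmr"] = {
            "n_snps": x.k,
            "egger_intercept": {
                "intercept": het.egger_intercept,
                "se": het.intercept_se,
                "pval": het.intercept_pval,
            },
            "conditional_f": {},
        }
        for label in x.exposure_labels:
            f, p = conditional_f(x, label)
            diagnostics["mvmr"]["conditional_f"][label] = {
                "F": f, "pval": p,
                "definition": "Q_x/(k-m+1); p = chi2 upper tail of Q_x, df k-m+1 "
                              "(null: no conditional instrument signal)",
            }
        return rows
    except StageError:
        raise
    except Exception as exc:
        raise StageError("mvmr", exc) from exc


def _write_run_log(out: Path, config: dict, seed: int) -> None:
    import scipy
    import statsmodels

    lines = [
        f"mrkit {__version__}",
        f"numpy {np.__version__}",
        f"pandas {pd.__version__}",
        f"scipy {scipy.__version__}",
        f"statsmodels {statsmodels.__version__}",
        f"seed {seed}",
        "config " + json.dumps(config, sort_keys=True, default=str),
    ]
    (out / "run.log").write_text("\n".join(lines) + "\n")
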