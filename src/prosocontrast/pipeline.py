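"""End-to-end pipeline: ingest or simulate -> filter -> classify -> score ->
fit, with a structured, reproducible report.

Identical configuration + seed yields a byte-identical JSON report, so
provenance deliberately records the resolved configuration and package
version but no wall-clock timestamps.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import __version__
from .annotations import (
    Dataset,
    ParticipantMeta,
    TokenAnnotation,
    read_participants_csv,
    read_tokens_csv,
    write_participants_csv,
    write_tokens_csv,
)
from .boundary import (
    DEFAULT_LENGTH_THRESHOLD,
    DEFAULT_PITCH_THRESHOLD,
    FilterReport,
    Phrasing,
    PhrasingResult,
    classify_dataset,
    filter_tokens,
    results_frame,
)
from .errors import ConfigError, ProsoContrastError
from .praat import import_textgrid_tokens
from .scoring import ParticipantScore, score_table, scores_frame
from .simulate import GeneratorConfig, generate_dataset
from .stats import (
    CorrelationResult,
    FixedEffect,
    ModelFit,
    TTestResult,
    fit_lmm_log,
    fit_mixed_logit,
    spearman,
    t_test_raw,
)

logger = logging.getLogger("prosocontrast")

ALL_MODELS = ("glmm", "glmm-by-group", "lmm-duration", "lmm-f0")
REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Configuration of one pipeline run; exactly one input mode is active."""

    input_mode: str = "simulate"  # simulate | csv | textgrid
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    tokens_csv: Optional[str] = None
    participants_csv: Optional[str] = None
    textgrid: Optional[str] = None
    pitchtier: Optional[str] = None
    token_meta_csv: Optional[str] = None
    tier_config: Optional[dict] = None
    pitch_threshold: float = DEFAULT_PITCH_THRESHOLD
    length_threshold: float = DEFAULT_LENGTH_THRESHOLD
    models: tuple[str, ...] = ALL_MODELS
    pvalue_method: str = "normal"
    seed: Optional[int] = None
    out_dir: Optional[str] = None

    def validate(self) -> None:
        if self.input_mode not in ("simulate", "csv", "textgrid"):
            raise ConfigError(f"unknown input_mode {self.input_mode!r}")
        if self.input_mode == "csv" and not self.tokens_csv:
            raise ConfigError("csv mode requires tokens_csv")
        if self.input_mode == "textgrid" and not (
            self.textgrid and self.pitchtier and self.token_meta_csv
        ):
            raise ConfigError(
                "textgrid mode requires textgrid, pitchtier and token_meta_csv"
            )
        unknown = set(self.models) - set(ALL_MODELS)
        if unknown:
            raise ConfigError(f"unknown model selector(s): {sorted(unknown)}")

    def to_dict(self) -> dict:
        payload = dataclasses.asdict(self)
        payload["generator"] = self.generator.to_dict()
        payload["models"] = list(self.models)
        return payload

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        payload = dict(payload)
        if isinstance(payload.get("generator"), dict):
            payload["generator"] = GeneratorConfig.from_dict(payload["generator"])
        if "models" in payload:
            payload["models"] = tuple(payload["models"])
        return cls(**payload)


@dataclass
class RunReport:
    filter_report: FilterReport
    phrasing_table: dict
    scores: list[ParticipantScore]
    fits: dict[str, ModelFit]
    t_tests: dict
    correlations: dict
    provenance: dict

    def to_dict(self) -> dict:
        return {
            "schema_version": REPORT_SCHEMA_VERSION,
            "filter_report": {
                "n_input": self.filter_report.n_input,
                "n_retained": self.filter_report.n_retained,
                "n_removed_disfluent": self.filter_report.n_removed_disfluent,
                "n_removed_error": self.filter_report.n_removed_error,
                "retained_pct": self.filter_report.retained_pct,
            },
            "phrasing_table": self.phrasing_table,
            "scores": scores_frame(self.scores).to_dict(orient="records"),
            "fits": {name: fit.to_dict() for name, fit in self.fits.items()},
            "t_tests": {
                name: (res.to_dict() if isinstance(res, TTestResult) else res)
                for name, res in self.t_tests.items()
            },
            "correlations": {
                name: (res.to_dict() if isinstance(res, CorrelationResult) else res)
                for name, res in self.correlations.items()
            },
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunReport":
        fr = payload["filter_report"]
        scores = [
            ParticipantScore(
                participant_id=row["participant_id"],
                group=row["group"],
                n_given=row["n_given"],
                n_given_one_ap=row["n_given_one_ap"],
                n_contrastive=row["n_contrastive"],
                n_contrastive_two_ap=row["n_contrastive_two_ap"],
                phrasing_score=row["phrasing_score"],
                hinting_score=row["hinting_score"],
            )
            for row in payload["scores"]
        ]
        fits = {}
        for name, fit in payload["fits"].items():
            fits[name] = ModelFit(
                formula=fit["formula"],
                fixed_effects=[FixedEffect(**fe) for fe in fit["fixed_effects"]],
                variance_components=fit["variance_components"],
                log_likelihood=fit["log_likelihood"],
                aic=fit["aic"],
                n_obs=fit["n_obs"],
                n_params=fit["n_params"],
                converged=fit["converged"],
                kind=fit["kind"],
                message=fit.get("message", ""),
            )
        t_tests = {
            name: (TTestResult(**res) if "t" in res else res)
            for name, res in payload["t_tests"].items()
        }
        correlations = {
            name: (CorrelationResult(**res) if "rho" in res else res)
            for name, res in payload["correlations"].items()
        }
        return cls(
            filter_report=FilterReport(
                n_input=fr["n_input"],
                n_retained=fr["n_retained"],
                n_removed_disfluent=fr["n_removed_disfluent"],
                n_removed_error=fr["n_removed_error"],
            ),
            phrasing_table=payload["phrasing_table"],
            scores=scores,
            fits=fits,
            t_tests=t_tests,
            correlations=correlations,
            provenance=payload["provenance"],
        )


def _stage(name: str):
    """Decorator labelling stage failures with the stage name."""

    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except ProsoContrastError as exc:
                raise type(exc)(f"[stage: {name}] {exc}") from exc

        return inner

    return wrap


@_stage("ingest")
def _load_dataset(config: RunConfig) -> Dataset:
    if config.input_mode == "simulate":
        gen = config.generator
        if config.seed is not None:
            gen = dataclasses.replace(gen, seed=config.seed)
        return generate_dataset(gen)
    if config.input_mode == "csv":
        return read_tokens_csv(config.tokens_csv, config.participants_csv)
    return _load_textgrid_dataset(config)


def _load_textgrid_dataset(config: RunConfig) -> Dataset:
    fragments = import_textgrid_tokens(
        config.textgrid, config.pitchtier, config.tier_config
    )
    meta_rows = pd.read_csv(config.token_meta_csv)
    if len(meta_rows) != len(fragments):
        raise ConfigError(
            f"token metadata rows ({len(meta_rows)}) do not match TextGrid "
            f"tokens ({len(fragments)})"
        )
    tokens = []
    for frag, (_, row) in zip(fragments, meta_rows.iterrows()):
        tokens.append(
            TokenAnnotation(
                token_id=str(row.get("token_id", frag.token_id)),
                participant_id=str(row["participant_id"]),
                group=str(row["group"]),
                item_id=str(row["item_id"]),
                condition=str(row["condition"]),
                dur_s1=frag.dur_s1,
                dur_s2=frag.dur_s2,
                f0_l=frag.f0_l,
                f0_h=frag.f0_h,
                disfluent=bool(row.get("disfluent", False)),
                labeling_error=bool(row.get("labeling_error", False)),
            )
        )
    if config.participants_csv:
        participants = read_participants_csv(config.participants_csv)
    else:
        from .annotations import derive_participants

        participants = derive_participants(tokens)
    dataset = Dataset(
        tokens=tokens,
        participants=participants,
        provenance=[
            f"tokens imported from {config.textgrid} + {config.pitchtier}",
            f"token metadata from {config.token_meta_csv}",
        ],
    )
    dataset.validate()
    return dataset


def _phrasing_table(
    dataset: Dataset, results: list[PhrasingResult]
) -> dict:
    """Counts and percentages of ONE_AP/TWO_AP by group x condition."""
    by_id = {tok.token_id: tok for tok in dataset.tokens}
    table: dict[str, dict[str, dict[str, float]]] = {}
    for res in results:
        tok = by_id[res.token_id]
        cell = table.setdefault(tok.group, {}).setdefault(
            tok.condition, {"ONE_AP": 0, "TWO_AP": 0}
        )
        cell[res.label.value] += 1
    for group in table.values():
        for cell in group.values():
            total = cell["ONE_AP"] + cell["TWO_AP"]
            cell["pct_ONE_AP"] = 100.0 * cell["ONE_AP"] / total if total else 0.0
            cell["pct_TWO_AP"] = 100.0 * cell["TWO_AP"] / total if total else 0.0
    return table


def _model_frame(dataset: Dataset, results: list[PhrasingResult]) -> pd.DataFrame:
    frame = results_frame(dataset, results)
    frame["outcome"] = (frame["label"] == Phrasing.TWO_AP.value).astype(int)
    return frame


@_stage("fit")
def _fit_models(config: RunConfig, frame: pd.DataFrame) -> dict[str, ModelFit]:
    fits: dict[str, ModelFit] = {}
    if "glmm" in config.models:
        fits["glmm"] = fit_mixed_logit(frame, include_interaction=True)
    if "glmm-by-group" in config.models:
        for group in sorted(frame["group"].unique()):
            sub = frame[frame["group"] == group]
            fits[f"glmm_{group}"] = fit_mixed_logit(sub, include_interaction=False)
    if "lmm-duration" in config.models:
        fits["lmm_duration"] = fit_lmm_log(
            frame, "duration", pvalue_method=config.pvalue_method
        )
    if "lmm-f0" in config.models:
        fits["lmm_f0"] = fit_lmm_log(frame, "f0", pvalue_method=config.pvalue_method)
    return fits


def _group_values(participants: list[ParticipantMeta], attr: str) -> dict[str, list]:
    values: dict[str, list] = {"HC": [], "SZ": []}
    for meta in participants:
        value = getattr(meta, attr)
        if value is not None:
            values[meta.group].append(float(value))
    return values


def _t_tests(dataset: Dataset) -> dict:
    """Group comparisons (SZ vs HC) on participant-level measures."""
    out: dict = {}
    for attr, label in (
        ("hinting_score", "hinting"),
        ("total_time", "total_time"),
        ("speaking_turns", "speaking_turns"),
    ):
        values = _group_values(dataset.participants, attr)
        if len(values["SZ"]) >= 2 and len(values["HC"]) >= 2:
            out[label] = t_test_raw(values["SZ"], values["HC"])
        else:
            out[label] = {
                "skipped": f"insufficient {attr} metadata "
                f"(SZ n={len(values['SZ'])}, HC n={len(values['HC'])})"
            }
    return out


def _correlations(scores: list[ParticipantScore]) -> dict:
    out: dict = {}
    for group in ("SZ", "HC"):
        pairs = [
            (s.phrasing_score, s.hinting_score)
            for s in scores
            if s.group == group and s.hinting_score is not None
        ]
        key = f"phrasing_vs_hinting_{group}"
        if len(pairs) < 3:
            out[key] = {"skipped": f"fewer than 3 scored {group} participants"}
            continue
        x = [p for p, _ in pairs]
        y = [h for _, h in pairs]
        try:
            out[key] = spearman(x, y)
        except ProsoContrastError as exc:
            out[key] = {"skipped": str(exc)}
    return out


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order; write intermediate CSVs and the final
    JSON + markdown report when ``config.out_dir`` is set."""
    config.validate()
    out_dir = Path(config.out_dir) if config.out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)

    dataset = _load_dataset(config)
    logger.info("ingest: %d tokens, %d participants", len(dataset.tokens), len(dataset.participants))
    if out_dir:
        write_tokens_csv(dataset, out_dir / "tokens.csv")
        write_participants_csv(dataset, out_dir / "participants.csv")

    retained, filter_report = filter_tokens(dataset)
    logger.info(
        "filter: kept %d/%d tokens (%.2f%%)",
        filter_report.n_retained,
        filter_report.n_input,
        filter_report.retained_pct,
    )
    results = classify_dataset(
        retained, config.pitch_threshold, config.length_threshold
    )
    frame = _model_frame(retained, results)
    if out_dir:
        results_frame(retained, results).to_csv(out_dir / "detection.csv", index=False)
        (out_dir / "filter_report.json").write_text(
            json.dumps(
                {
                    "n_input": filter_report.n_input,
                    "n_retained": filter_report.n_retained,
                    "n_removed_disfluent": filter_report.n_removed_disfluent,
                    "n_removed_error": filter_report.n_removed_error,
                    "retained_pct": filter_report.retained_pct,
                },
                indent=2,
            )
        )

    scores = score_table(retained, results)
    logger.info("score: %d participants scored", len(scores))
    if out_dir:
        scores_frame(scores).to_csv(out_dir / "scores.csv", index=False)

    fits = _fit_models(config, frame) if config.models else {}
    t_tests = _t_tests(dataset)
    correlations = _correlations(scores)

    report = RunReport(
        filter_report=filter_report,
        phrasing_table=_phrasing_table(retained, results),
        scores=scores,
        fits=fits,
        t_tests=t_tests,
        correlations=correlations,
        provenance={
            "package": "prosocontrast",
            "version": __version__,
            "schema_version": REPORT_SCHEMA_VERSION,
            "config": config.to_dict(),
        },
    )
    if out_dir:
        (out_dir / "report.json").write_text(render_report(report, "json"))
        (out_dir / "report.md").write_text(render_report(report, "markdown"))
    return report


def render_report(report: RunReport, format: str = "json") -> str:
    """Serialise a report as canonical JSON or human-readable markdown."""
    if format == "json":
        return json.dumps(report.to_dict(), indent=2, sort_keys=True) + "\n"
    if format != "markdown":
        raise ValueError(f"unknown report format {format!r}")
    return _render_markdown(report)


def _render_markdown(report: RunReport) -> str:
    lines: list[str] = ["# Prosodic phrasing pipeline report", ""]
    fr = report.filter_report
    lines += [
        "## Token filtering",
        "",
        f"- tokens in: {fr.n_input}",
        f"- retained: {fr.n_retained} ({fr.retained_pct:.2f}%)",
        f"- removed (disfluent): {fr.n_removed_disfluent}",
        f"- removed (labeling error): {fr.n_removed_error}",
        "",
        "## Phrasing by group and condition",
        "",
    ]
    if report.phrasing_table:
        lines += [
            "| Group | Condition | 1 AP | 2 APs | % 1 AP | % 2 APs |",
            "| --- | --- | --- | --- | --- | --- |",
        ]
        for group in sorted(report.phrasing_table):
            for condition in sorted(report.phrasing_table[group]):
                cell = report.phrasing_table[group][condition]
                lines.append(
                    f"| {group} | {condition} | {cell['ONE_AP']} | {cell['TWO_AP']} "
                    f"| {cell['pct_ONE_AP']:.1f} | {cell['pct_TWO_AP']:.1f} |"
                )
    else:
        lines.append("*(table absent: no classified tokens)*")
    lines.append("")

    lines += ["## Participant scores", ""]
    if report.scores:
        lines += [
            "| Participant | Group | Phrasing score (0-20) | Hinting score (0-20) |",
            "| --- | --- | --- | --- |",
        ]
        for s in report.scores:
            hint = "-" if s.hinting_score is None else str(s.hinting_score)
            lines.append(
                f"| {s.participant_id} | {s.group} | {s.phrasing_score:.2f} | {hint} |"
            )
    else:
        lines.append("*(table absent: no scored participants)*")
    lines.append("")

    lines += ["## Model fits", ""]
    if report.fits:
        for name, fit in report.fits.items():
            stat_label = "z" if fit.kind == "glmm" else "t"
            lines += [
                f"### {name}",
                "",
                f"response: {fit.formula['response']}; "
                f"random intercepts: {', '.join(fit.formula['random_intercepts'])}; "
                f"n = {fit.n_obs}; AIC = {fit.aic:.1f}; "
                f"log-likelihood = {fit.log_likelihood:.2f}; "
                f"converged = {fit.converged}",
                "",
                "**Random effects (variances)**",
                "",
            ]
            for comp, var in fit.variance_components.items():
                lines.append(f"- {comp}: {var:.5f}")
            lines += [
                "",
                f"| Fixed effect | Estimate | Std. error | {stat_label} | p |",
                "| --- | --- | --- | --- | --- |",
            ]
            for fe in fit.fixed_effects:
                lines.append(
                    f"| {fe.name} | {fe.estimate:.4f} | {fe.std_error:.4f} "
                    f"| {fe.statistic:.3f} | {fe.p_value:.4g} |"
                )
            lines.append("")
    else:
        lines += ["*(tables absent: no models fitted)*", ""]

    lines += ["## Group comparisons (SZ vs HC)", ""]
    for name, res in report.t_tests.items():
        if isinstance(res, TTestResult):
            lines.append(
                f"- {name}: t({res.df:.0f}) = {res.t:.2f}, p = {res.p_value:.4g} "
                f"(SZ {res.mean_1:.2f} ± {res.sd_1:.2f}, HC {res.mean_2:.2f} ± {res.sd_2:.2f})"
            )
        else:
            lines.append(f"- {name}: skipped ({res['skipped']})")
    lines.append("")

    lines += ["## Correlations", ""]
    for name, res in report.correlations.items():
        if isinstance(res, CorrelationResult):
            lines.append(f"- {name}: rho = {res.rho:.3f} (n = {res.n}, p = {res.p_value:.4g})")
        else:
            lines.append(f"- {name}: skipped ({res['skipped']})")
    lines.append("")
    return "\n".join(lines)
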