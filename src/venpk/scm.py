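"""Stepwise covariate modelling by likelihood-ratio thresholds.

Forward inclusion accepts, at each round, the candidate covariate-parameter
relation with the largest drop in objective function value, provided that
drop exceeds 6.63 (chi-square, p < 0.01, df = 1; strict inequality).
After forward exhaustion, each retained relation is removed from the full
model one at a time and kept only if its removal raises the OFV by more
than 10.83 (p < 0.001).  The search is deterministic given the dataset:
ties between equal candidates break lexicographically on
(parameter, covariate).
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .covariates import CovariateEffect
from .data import Dataset
from .engine import Design
from .estimate import FitOptions, FitResult, ModelSpec, fit
from .errors import ValidationError

FORWARD_DOFV = 6.63
BACKWARD_DOFV = 10.83

_BINARY_COVARIATES = (
    "morbid", "formulation", "sex", "smoking", "drinking",
    "valproic_acid", "quetiapine", "clozapine", "olanzapine",
    "risperidone", "amisulpride",
)
_CONTINUOUS_COVARIATES = ("age", "weight")
_DISPOSITION_PARAMS = ("cl_f", "v_f", "clm_f", "vm_f")


@dataclass(frozen=True)
class TraceEntry:
    step: str  # "forward" | "backward"
    parameter: str
    covariate: str
    ofv_reference: float
    ofv_candidate: float
    delta_ofv: float
    accepted: bool
    note: str = ""


@dataclass
class SearchTrace:
    entries: list[TraceEntry] = field(default_factory=list)

    def add(self, entry: TraceEntry) -> None:
        self.entries.append(entry)

    def to_json(self) -> str:
        return json.dumps([dataclasses.asdict(e) for e in self.entries], indent=1)

    @classmethod
    def from_json(cls, text: str) -> "SearchTrace":
        return cls([TraceEntry(**e) for e in json.loads(text)])

    def to_tsv(self) -> str:
        cols = [f.name for f in dataclasses.fields(TraceEntry)]
        lines = ["\t".join(cols)]
        for e in self.entries:
            lines.append("\t".join(repr(getattr(e, c)) for c in cols))
        return "\n".join(lines) + "\n"

    def write(self, stem: str | Path) -> None:
        stem = Path(stem)
        stem.with_suffix(".json").write_text(self.to_json())
        stem.with_suffix(".tsv").write_text(self.to_tsv())


def default_candidate_grid(
    dataset: Dataset,
    parameters: tuple[str, ...] = _DISPOSITION_PARAMS,
) -> list[CovariateEffect]:
    """Full candidate grid minus structurally confounded pairs.

    Health status is only tested on the parent-drug parameters: the
    intensive healthy study contributes no metabolite observations, so a
    morbid effect on a metabolite parameter is confounded with that
    parameter's own typical value.  Continuous covariates enter as power
    functions normalised to the pooled median.
    """
    obs = dataset.df[dataset.df["EVID"] == 0]
    candidates: list[CovariateEffect] = []
    for par in parameters:
        for cov in _BINARY_COVARIATES:
            if cov == "morbid" and par in ("clm_f", "vm_f"):
                continue
            candidates.append(CovariateEffect(par, cov, "linear", 0.0))
        for cov in _CONTINUOUS_COVARIATES:
            col = {"age": "AGE", "weight": "WT"}[cov]
            ref = float(obs[col].median())
            candidates.append(CovariateEffect(par, cov, "power", 0.0, ref))
    return candidates


def _sorted_candidates(candidates) -> list[CovariateEffect]:
    return sorted(candidates, key=lambda e: (e.parameter, e.covariate))


def forward_step(
    dataset: Dataset,
    model: ModelSpec,
    candidates: list[CovariateEffect],
    base_fit: FitResult | None = None,
    options: FitOptions | None = None,
    threshold: float = FORWARD_DOFV,
    design: Design | None = None,
):
    """One forward-inclusion round.

    Fits every candidate added to ``model``; returns
    ``(best_candidate_fit_or_None, trace_entries)``.  A candidate is
    accepted only when its OFV drop strictly exceeds the threshold; the
    largest drop wins, ties break lexicographically.
    """
    if design is None:
        design = Design.from_dataset(dataset)
    if base_fit is None:
        base_fit = fit(dataset, model, options, design=design)
    entries: list[TraceEntry] = []
    best: tuple[float, CovariateEffect, FitResult] | None = None
    for cand in _sorted_candidates(candidates):
        try:
            cand_fit = fit(dataset, base_fit.model.with_effect(cand), options, design=design)
        except Exception as exc:  # candidate fit failure: skip with warning
            warnings.warn(f"candidate {cand.covariate}->{cand.parameter} failed: {exc}")
            entries.append(TraceEntry(
                "forward", cand.parameter, cand.covariate,
                base_fit.ofv, float("nan"), float("nan"), False, f"fit failed: {exc}",
            ))
            continue
        dofv = base_fit.ofv - cand_fit.ofv
        accept = dofv > threshold and (best is None or dofv > best[0])
        entries.append(TraceEntry(
            "forward", cand.parameter, cand.covariate,
            base_fit.ofv, cand_fit.ofv, dofv, False,
        ))
        if accept:
            best = (dofv, cand, cand_fit)
    if best is None:
        return None, entries
    dofv, cand, cand_fit = best
    for i, e in enumerate(entries):
        if e.parameter == cand.parameter and e.covariate == cand.covariate:
            entries[i] = replace(e, accepted=True)
    return (cand, cand_fit), entries


def backward_step(
    dataset: Dataset,
    full_fit: FitResult,
    options: FitOptions | None = None,
    threshold: float = BACKWARD_DOFV,
    design: Design | None = None,
):
    """Backward elimination against the full model.

    Each covariate effect is removed one at a time (independently); it is
    retained only when its removal raises the OFV by more than the
    threshold.  Returns ``(final_fit, trace_entries)``; the final model is
    refitted when anything was dropped.
    """
    if design is None:
        design = Design.from_dataset(dataset)
    model = full_fit.model
    entries: list[TraceEntry] = []
    dropped: list[tuple[str, str]] = []
    for eff in sorted(model.covariate_effects, key=lambda e: (e.parameter, e.covariate)):
        reduced = model.without_effect(eff.key)
        try:
            red_fit = fit(dataset, reduced, options, design=design)
        except Exception as exc:
            warnings.warn(f"reduced fit without {eff.covariate}->{eff.parameter} "
                          f"failed: {exc}")
            entries.append(TraceEntry(
                "backward", eff.parameter, eff.covariate,
                full_fit.ofv, float("nan"), float("nan"), True, f"fit failed: {exc}",
            ))
            continue
        dofv = red_fit.ofv - full_fit.ofv  # rise in OFV caused by removal
        keep = dofv > threshold
        entries.append(TraceEntry(
            "backward", eff.parameter, eff.covariate,
            full_fit.ofv, red_fit.ofv, dofv, keep,
        ))
        if not keep:
            dropped.append(eff.key)
    if not dropped:
        return full_fit, entries
    final_model = model
    for key in dropped:
        final_model = final_model.without_effect(key)
    final_fit = fit(dataset, final_model, options, design=design)
    return final_fit, entries


def stepwise_search(
    dataset: Dataset,
    base_model: ModelSpec,
    candidates: list[CovariateEffect] | None = None,
    options: FitOptions | None = None,
    forward_threshold: float = FORWARD_DOFV,
    backward_threshold: float = BACKWARD_DOFV,
):
    """Forward inclusion to exhaustion, then one backward-elimination pass.

    Returns ``(final_fit, SearchTrace)``.  With no candidates the base fit
    is returned unchanged (empty trace).
    """
    design = Design.from_dataset(dataset)
    if candidates is None:
        candidates = default_candidate_grid(dataset)
    trace = SearchTrace()
    current_fit = fit(dataset, base_model, options, design=design)
    remaining = list(candidates)
    while remaining:
        result, entries = forward_step(
            dataset, current_fit.model, remaining, base_fit=current_fit,
            options=options, threshold=forward_threshold, design=design,
        )
        for e in entries:
            trace.add(e)
        if result is None:
            break
        cand, current_fit = result
        remaining = [c for c in remaining if c.key != cand.key]
    if current_fit.model.covariate_effects:
        current_fit, entries = backward_step(
            dataset, current_fit, options=options,
            threshold=backward_threshold, design=design,
        )
        for e in entries:
            trace.add(e)
    return current_fit, trace
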