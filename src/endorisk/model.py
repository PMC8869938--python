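"""Classifier evaluation as model/results objects.

:class:`RiskStratification` is built from a cohort plus a risk scheme and
endpoint; ``fit()`` runs the whole evaluation — group distribution,
per-group Kaplan–Meier 5-year rates with confidence bands, the ordinal
Cox fit (one hazard ratio per severity step), the concordance index of
the ordinal score, and the k-group log-rank test — and returns a
:class:`RiskStratificationResults` with a ``summary()`` table.

On top of these sit the comparison utilities: reclassification
(Sankey-style) transition matrices between schemes, the biomarker screen
on the merged 2020 intermediate groups, and the side-by-side evaluation
of the three-tier CTNNB1 proposal against the four-group 2020 scheme.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.iolib.table import SimpleTable

from .classifiers import (
    PoleWhitelist,
    classify_cohort,
    classify_proposal,
    is_unclassifiable,
)
from .cohort import Cohort
from .simulate import GROUP_DEFAULTS
from .survival import (
    ConcordanceResult,
    CoxFit,
    CoxNoFitError,
    KMCurve,
    LogrankResult,
    concordance,
    cox_ordinal_by_group,
    endpoint_arrays,
    km_estimate,
    logrank_test,
    survival_at,
    univariate_screen,
)

__all__ = [
    "RiskStratification",
    "RiskStratificationResults",
    "TransitionMatrix",
    "ProposalEvaluation",
    "sankey_matrix",
    "merged_intermediate_screen",
    "evaluate_proposal",
    "build_classifier_report",
]


def _ci_at(curve: KMCurve, t: float) -> tuple[float, float]:
    """Pointwise log–log CI of S(t) by the same step lookup as survival_at."""
    idx = np.searchsorted(curve.event_times, t, side="right") - 1
    if idx < 0:
        return (1.0, 1.0)
    return (float(curve.ci_low[idx]), float(curve.ci_high[idx]))


class RiskStratification:
    """Evaluate one risk-stratification scheme on a cohort.

    Parameters
    ----------
    cohort : Cohort
        Validated patient table.  Molecular NE states should be resolved
        (imputed) beforehand; unclassifiable patients are excluded from
        the survival statistics and counted in the results' notes.
    scheme : {"c2016", "promise", "c2020", "proposal"}
    endpoint : {"rfs", "os"}
    labels : sequence, optional
        Precomputed group labels; by default the scheme's engine is run.
    ties : {"efron", "breslow"}
        Tie handling for the Cox partial likelihood.
    """

    def __init__(
        self,
        cohort: Cohort,
        scheme: str = "c2020",
        endpoint: str = "rfs",
        labels=None,
        whitelist: PoleWhitelist | None = None,
        ties: str = "efron",
    ):
        if scheme not in GROUP_DEFAULTS:
            raise ValueError(f"unknown scheme {scheme!r}")
        self.cohort = cohort
        self.scheme = scheme
        self.endpoint = endpoint
        self.ties = ties
        self.group_order = list(GROUP_DEFAULTS[scheme]["groups"])
        if labels is None:
            labels = classify_cohort(cohort, scheme, whitelist)
        self.labels = pd.Series(list(labels), index=cohort.df.index)

    @classmethod
    def from_csv(cls, path, **kwargs) -> "RiskStratification":
        from .cohort import read_cohort

        return cls(read_cohort(path), **kwargs)

    def fit(self) -> "RiskStratificationResults":
        time, event = endpoint_arrays(self.cohort, self.endpoint)
        ok = ~self.labels.map(is_unclassifiable).to_numpy(dtype=bool)
        notes: list[str] = []
        n_uncls = int((~ok).sum())
        if n_uncls:
            for reason, cnt in self.labels[~ok].value_counts().items():
                notes.append(f"{cnt} patient(s) excluded: {reason}")
        labels = self.labels[ok]
        time, event = time[ok], event[ok]

        present = [g for g in self.group_order if (labels == g).any()]
        for g in self.group_order:
            if g not in present:
                notes.append(f"group '{g}' is empty; ordinal coding skips its rank")

        km_curves: dict[str, KMCurve] = {}
        rows = []
        n_classified = len(labels)
        for g in present:
            mask = (labels == g).to_numpy()
            curve = km_estimate(time[mask], event[mask])
            km_curves[g] = curve
            with warnings.catch_warnings():
                # extrapolation warning when a small group's follow-up ends
                # before 60 months; the rate is still the last step value
                warnings.simplefilter("ignore")
                rate = survival_at(curve, 60.0)
            lo, hi = _ci_at(curve, 60.0)
            rows.append(
                {
                    "group": g,
                    "n": int(mask.sum()),
                    "percent": 100.0 * mask.sum() / n_classified,
                    "n_events": int(event[mask].sum()),
                    "five_year_rate": 100.0 * rate,
                    "rate_ci_low": 100.0 * lo,
                    "rate_ci_high": 100.0 * hi,
                }
            )
        group_table = pd.DataFrame(rows)

        cox = conc = lr = None
        if len(present) >= 2 and event.sum() > 0:
            try:
                cox = cox_ordinal_by_group(
                    labels, time, event, self.group_order, ties=self.ties
                )
            except CoxNoFitError as exc:
                notes.append(f"ordinal Cox not fitted: {exc}")
            score_map = {g: i + 1 for i, g in enumerate(present)}
            scores = labels.map(score_map).to_numpy(dtype=float)
            try:
                conc = concordance(scores, time, event)
            except ValueError as exc:
                notes.append(f"concordance undefined: {exc}")
            try:
                lr = logrank_test(labels, time, event)
            except ValueError as exc:
                notes.append(f"log-rank not run: {exc}")
        else:
            notes.append("fewer than 2 groups (or no events): distribution only")

        return RiskStratificationResults(
            scheme=self.scheme,
            endpoint=self.endpoint,
            n=len(self.cohort),
            n_classified=n_classified,
            n_unclassifiable=n_uncls,
            group_table=group_table,
            km_curves=km_curves,
            cox=cox,
            concordance=conc,
            logrank=lr,
            notes=notes,
            labels=self.labels,
        )


@dataclass
class RiskStratificationResults:
    """Fitted evaluation of one scheme on one endpoint."""

    scheme: str
    endpoint: str
    n: int
    n_classified: int
    n_unclassifiable: int
    group_table: pd.DataFrame
    km_curves: dict
    cox: CoxFit | None
    concordance: ConcordanceResult | None
    logrank: LogrankResult | None
    notes: list = field(default_factory=list)
    labels: pd.Series | None = None

    @property
    def c_index(self) -> float | None:
        return None if self.concordance is None else self.concordance.c_index

    def five_year_rate(self, group: str) -> float:
        """KM 5-year survival for ``group``, as a percentage."""
        row = self.group_table[self.group_table["group"] == group]
        if row.empty:
            raise KeyError(f"group {group!r} not present")
        return float(row["five_year_rate"].iloc[0])

    def summary(self) -> str:
        head = [
            f"Risk stratification evaluation — scheme: {self.scheme}, "
            f"endpoint: {self.endpoint.upper()}",
            f"n = {self.n} ({self.n_classified} classified"
            + (f", {self.n_unclassifiable} unclassifiable)" if self.n_unclassifiable else ")"),
        ]
        rows = [
            [
                r["group"],
                f"{r['n']} ({r['percent']:.1f}%)",
                f"{r['five_year_rate']:.1f}",
                f"({r['rate_ci_low']:.1f}-{r['rate_ci_high']:.1f})",
                str(r["n_events"]),
            ]
            for _, r in self.group_table.iterrows()
        ]
        table = SimpleTable(
            rows,
            headers=["group", "n (%)", "5-yr rate (%)", "95% CI", "events"],
            title=None,
        )
        lines = head + [str(table)]
        if self.cox is not None:
            lo, hi = self.cox.ci95
            lines.append(
                f"Ordinal Cox ({self.cox.ties} ties): HR per step {self.cox.hr:.2f} "
                f"(95% CI {lo:.2f}-{hi:.2f}), p = {self.cox.p_value:.2g}"
            )
            lines.append(f"  coding: {self.cox.covariate_coding}")
        if self.concordance is not None:
            lines.append(f"c-index = {self.concordance.c_index:.2f}")
        if self.logrank is not None:
            lines.append(
                f"log-rank chi2 = {self.logrank.statistic:.2f} "
                f"(df={self.logrank.df}), p = {self.logrank.p_value:.2g}"
            )
        lines += [f"note: {n}" for n in self.notes]
        return "\n".join(lines)

    def to_dict(self) -> dict:
        """JSON-serialisable report (the data of record; plots are renders)."""
        out = {
            "scheme": self.scheme,
            "endpoint": self.endpoint,
            "n": self.n,
            "n_classified": self.n_classified,
            "n_unclassifiable": self.n_unclassifiable,
            "groups": self.group_table.to_dict(orient="records"),
            "notes": list(self.notes),
        }
        if self.cox is not None:
            out["ordinal_cox"] = {
                "hr": self.cox.hr,
                "ci95": list(self.cox.ci95),
                "p_value": self.cox.p_value,
                "coding": self.cox.covariate_coding,
                "converged": self.cox.converged,
            }
        if self.concordance is not None:
            out["c_index"] = self.concordance.c_index
            out["pair_counts"] = {
                "concordant": self.concordance.concordant,
                "discordant": self.concordance.discordant,
                "tied": self.concordance.tied,
                "permissible": self.concordance.permissible,
            }
        if self.logrank is not None:
            out["logrank"] = {
                "statistic": self.logrank.statistic,
                "df": self.logrank.df,
                "p_value": self.logrank.p_value,
            }
        return out


def build_classifier_report(
    cohort: Cohort, scheme: str, endpoint: str = "rfs", **kwargs
) -> RiskStratificationResults:
    """Functional alias: ``RiskStratification(cohort, scheme, endpoint).fit()``."""
    return RiskStratification(cohort, scheme=scheme, endpoint=endpoint, **kwargs).fit()


# ---------------------------------------------------------------------------
# Reclassification flow


@dataclass(frozen=True)
class TransitionMatrix:
    """Patient reclassification counts between two schemes."""

    from_scheme: str
    to_scheme: str
    counts: pd.DataFrame  # rows: from-groups, cols: to-groups

    @property
    def total(self) -> int:
        return int(self.counts.to_numpy().sum())

    @property
    def row_marginals(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> pd.Series:
        return self.counts.sum(axis=0)

    def to_sankey_payload(self) -> dict:
        """``{nodes, links}`` payload for common Sankey renderers."""
        from_nodes = [f"{self.from_scheme}:{g}" for g in self.counts.index]
        to_nodes = [f"{self.to_scheme}:{g}" for g in self.counts.columns]
        nodes = from_nodes + to_nodes
        links = []
        for i, g_from in enumerate(self.counts.index):
            for j, g_to in enumerate(self.counts.columns):
                v = int(self.counts.iloc[i, j])
                if v:
                    links.append(
                        {"source": i, "target": len(from_nodes) + j, "value": v}
                    )
        return {"nodes": [{"name": n} for n in nodes], "links": links}


def sankey_matrix(
    labels_a, labels_b, from_scheme: str = "a", to_scheme: str = "b"
) -> TransitionMatrix:
    """Contingency matrix of patients classified under both schemes."""
    a = pd.Series(list(labels_a))
    b = pd.Series(list(labels_b))
    if len(a) != len(b):
        raise ValueError("label vectors differ in length")
    order_a = [g for g in GROUP_DEFAULTS.get(from_scheme, {}).get("groups", []) if (a == g).any()] or sorted(a.unique())
    order_b = [g for g in GROUP_DEFAULTS.get(to_scheme, {}).get("groups", []) if (b == g).any()] or sorted(b.unique())
    counts = pd.crosstab(a, b).reindex(index=order_a, columns=order_b, fill_value=0)
    counts.index.name = from_scheme
    counts.columns.name = to_scheme
    return TransitionMatrix(from_scheme, to_scheme, counts)


# ---------------------------------------------------------------------------
# Biomarker screen on the merged 2020 intermediate groups


def merged_intermediate_screen(
    cohort: Cohort,
    biomarkers: list[str] | None = None,
    labels2020=None,
    endpoints: tuple = ("rfs", "os"),
) -> pd.DataFrame:
    """Univariate Cox screen restricted to the merged 2020 intermediate set.

    The 2020 intermediate and high-intermediate groups are pooled into a
    single subset, and each biomarker is fitted univariately (complete-case
    per biomarker) for the requested endpoints.
    """
    if biomarkers is None:
        biomarkers = ["er", "pr", "ecad", "her2", "arid1a", "pten", "l1cam", "ctnnb1_exon3"]
    if labels2020 is None:
        labels2020 = classify_cohort(cohort, "c2020")
    labels2020 = pd.Series(list(labels2020), index=cohort.df.index)
    mask = labels2020.isin(["intermediate", "high_intermediate"]).to_numpy()
    if not mask.any():
        raise ValueError("no patients in the merged intermediate groups")
    tables = [
        univariate_screen(cohort, biomarkers, endpoint=ep, subgroup_mask=mask)
        for ep in endpoints
    ]
    return pd.concat(tables, ignore_index=True)


# ---------------------------------------------------------------------------
# Three-tier proposal evaluation


@dataclass
class ProposalEvaluation:
    """Side-by-side evaluation of the 2020 scheme and the CTNNB1 proposal."""

    results_2020: RiskStratificationResults
    results_proposal: RiskStratificationResults

    @property
    def c_index_delta(self) -> float:
        return self.results_proposal.c_index - self.results_2020.c_index

    def summary(self) -> str:
        parts = [
            self.results_2020.summary(),
            "",
            self.results_proposal.summary(),
            "",
            f"c-index delta (proposal - 2020): {self.c_index_delta:+.3f}",
        ]
        return "\n".join(parts)


def evaluate_proposal(
    cohort: Cohort,
    endpoint: str = "rfs",
    whitelist: PoleWhitelist | None = None,
    ties: str = "efron",
) -> ProposalEvaluation:
    """Evaluate the four-group 2020 scheme and its three-tier CTNNB1
    refinement on the identical patient set.

    Both reports are built from one run of the 2020 engine so the low and
    high groups are shared by construction; the proposal relabels the
    intermediate tiers from the CTNNB1 exon-3 status.
    """
    labels2020 = classify_cohort(cohort, "c2020", whitelist)
    ctnnb1 = cohort.df["ctnnb1_exon3"]
    labels_prop = pd.Series(
        [classify_proposal(g, c) for g, c in zip(labels2020, ctnnb1)],
        index=cohort.df.index,
        name="proposal_group",
    )
    res_2020 = RiskStratification(
        cohort, "c2020", endpoint, labels=labels2020, ties=ties
    ).fit()
    res_prop = RiskStratification(
        cohort, "proposal", endpoint, labels=labels_prop, ties=ties
    ).fit()
    return ProposalEvaluation(res_2020, res_prop)
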