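"""Reverse mapping from embedding clusters to natural language.

An embedding vector cannot be inverted back to its source text, so
clusters are explained indirectly: group the original code strings by
cluster membership and ask a text-generating model to label each group.
The prompt builder and the structured-response parser implement that
contract offline; actual LLM backends plug in behind a ``labeler``
callable, and a deterministic stub (labels = the cluster's most
over-represented codes by lift) makes the pipeline runnable and
testable without network access.

The second half of the module quantifies cluster/outcome association:
Kendall's tau-b between the binary membership indicator of each
cluster and each AKI outcome, with Bonferroni adjustment over
m = outcomes x clusters tests.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, ValidationError
from scipy import stats

from .cluster_metrics import greedy_cluster_mapping
from .ehr_text import parse_field
from .outcomes import OUTCOME_COLUMNS

FIELD_DISPLAY = {"diagnosis": "Diagnoses", "operation": "Operations"}
MEMBER_JOINER = " || "


@dataclass
class LabelPrompt:
    preamble: str
    body: str
    token_estimate: int

    @property
    def text(self) -> str:
        return f"{self.preamble}\n\n{self.body}"


def build_label_prompt(
    texts: dict[str, list[str]],
    assignment,
    fields: tuple[str, ...] = ("diagnosis", "operation"),
    member_cap: int | None = None,
) -> LabelPrompt:
    """Cluster-labeling prompt: a preamble stating the task and a body
    listing every member under its "Group N:" section.

    Member lines render each requested field as "FieldName: codes",
    joined by " || ".  Groups are numbered from 1.  An empty cluster
    keeps its section (with zero members).  ``member_cap`` optionally
    truncates long clusters with an ellipsis marker.
    """
    assignment = np.asarray(assignment)
    n = assignment.size
    for field in fields:
        if field not in texts or len(texts[field]) != n:
            raise ValueError(f"texts for field {field!r} must cover all {n} rows")
    k = int(assignment.max()) + 1 if n else 0
    field_desc = " and ".join(FIELD_DISPLAY.get(f, f).lower() for f in fields)
    preamble = (
        f"The following is a list of {n} pediatric patients undergoing "
        f"cardiopulmonary bypass. Each row lists the patient's {field_desc}, "
        f"with entries separated by ';'. Patients have been grouped into {k} "
        "groups according to these fields. Please suggest group labels that "
        "are representative of their members, and also distinct from each other:"
    )
    sections = []
    for j in range(k):
        members = np.flatnonzero(assignment == j)
        lines = [f"Group {j + 1}:"]
        shown = members if member_cap is None else members[:member_cap]
        for i in shown:
            parts = [
                f"{FIELD_DISPLAY.get(f, f)}: {texts[f][i]}" for f in fields
            ]
            lines.append(MEMBER_JOINER.join(parts))
        if member_cap is not None and len(members) > member_cap:
            lines.append("...")
        sections.append("\n".join(lines))
    body = "\n=======\n".join(sections)
    full = f"{preamble}\n\n{body}"
    return LabelPrompt(preamble=preamble, body=body, token_estimate=len(full) // 4)


class _LabelEntry(BaseModel):
    group_number: int
    short_label: str
    long_label: str


@dataclass
class ClusterLabelSet:
    """Per-cluster labels with provenance."""

    labels: dict[int, dict[str, str]]
    source: str
    run_id: int = 0


def parse_label_response(response: str, k: int, source: str = "adapter") -> ClusterLabelSet:
    """Parse a structured (JSON) labeling response.

    Expects a JSON array of ``{group_number, short_label, long_label}``
    objects, exactly one per group 1..k; missing or duplicate group
    numbers are parse errors with diagnostics.
    """
    try:
        raw = json.loads(response)
    except json.JSONDecodeError as exc:
        raise ValueError(f"label response is not valid JSON: {exc}") from exc
    if not isinstance(raw, list):
        raise ValueError("label response must be a JSON array")
    try:
        entries = [_LabelEntry.model_validate(item) for item in raw]
    except ValidationError as exc:
        raise ValueError(f"malformed label entry: {exc}") from exc
    numbers = [e.group_number for e in entries]
    dupes = [g for g, c in Counter(numbers).items() if c > 1]
    if dupes:
        raise ValueError(f"duplicate group numbers in response: {sorted(dupes)}")
    missing = sorted(set(range(1, k + 1)) - set(numbers))
    if missing or len(entries) != k:
        raise ValueError(
            f"expected one label per group 1..{k}; missing {missing}, got {sorted(numbers)}"
        )
    return ClusterLabelSet(
        labels={
            e.group_number - 1: {"short_label": e.short_label, "long_label": e.long_label}
            for e in entries
        },
        source=source,
    )


def stub_labeler(
    texts: dict[str, list[str]],
    assignment,
    fields: tuple[str, ...] = ("diagnosis", "operation"),
    top: int = 3,
) -> str:
    """Deterministic offline labeler: each cluster is labeled by its
    ``top`` most over-represented codes (by lift = within-cluster rate /
    overall rate).  Returns a structured JSON response, so it doubles
    as a fixture for :func:`parse_label_response`."""
    assignment = np.asarray(assignment)
    k = int(assignment.max()) + 1
    row_codes = [
        set().union(*(parse_field(texts[f][i]).codes for f in fields))
        for i in range(assignment.size)
    ]
    overall = Counter(c for codes in row_codes for c in codes)
    n = assignment.size
    entries = []
    for j in range(k):
        members = np.flatnonzero(assignment == j)
        counts = Counter(c for i in members for c in row_codes[i])
        if not counts:
            entries.append(
                {"group_number": j + 1, "short_label": f"empty group {j + 1}",
                 "long_label": "No members."}
            )
            continue
        m = len(members)
        lift = {
            c: (cnt / m) / (overall[c] / n) for c, cnt in counts.items()
        }
        ranked = sorted(lift, key=lambda c: (-lift[c], c))[:top]
        entries.append(
            {
                "group_number": j + 1,
                "short_label": ", ".join(ranked),
                "long_label": f"Cluster characterized by over-represented codes: "
                              f"{', '.join(ranked)}.",
            }
        )
    return json.dumps(entries, indent=1)


def align_labels(runs: list[tuple[np.ndarray, ClusterLabelSet]]) -> pd.DataFrame:
    """Align label sets from several clustering runs onto run 0's ids.

    Each run's clusters are mapped to run 0 by greedy member-overlap
    matching; the returned table has one row per run-0 cluster and one
    short-label column per run.
    """
    if len(runs) < 2:
        raise ValueError("alignment needs at least 2 runs")
    n = len(np.asarray(runs[0][0]))
    for assignment, _ in runs:
        if len(np.asarray(assignment)) != n:
            raise ValueError("all runs must cover the same rows")
    ref_assignment = np.asarray(runs[0][0])
    ref_ids = sorted(np.unique(ref_assignment).tolist())
    table: dict[str, list] = {"cluster": ref_ids}
    for r, (assignment, label_set) in enumerate(runs):
        mapping = greedy_cluster_mapping(np.asarray(assignment), ref_assignment).mapping
        inverse = {ref: own for own, ref in mapping.items()}
        table[f"run_{r}"] = [
            label_set.labels.get(inverse[ref], {}).get("short_label")
            if ref in inverse
            else None
            for ref in ref_ids
        ]
    return pd.DataFrame(table)


def outcome_cluster_correlation(
    assignment,
    outcomes: pd.DataFrame,
    alpha: float = 0.05,
    outcome_columns: list[str] | None = None,
) -> pd.DataFrame:
    """Kendall tau-b of cluster membership with each AKI outcome.

    For each (outcome, cluster) pair, tau-b is computed between the
    binary in-cluster indicator and the outcome values, with raw
    p-values and Bonferroni-adjusted significance at
    m = outcomes x clusters tests.  A constant outcome yields missing
    tau with a note.
    """
    assignment = np.asarray(assignment)
    cols = outcome_columns or [c for c in OUTCOME_COLUMNS if c in outcomes.columns]
    if len(outcomes) != assignment.size:
        raise ValueError("outcomes must be computed for all rows")
    clusters = sorted(np.unique(assignment).tolist())
    m = len(cols) * len(clusters)
    rows = []
    for outcome in cols:
        values = outcomes[outcome].to_numpy(dtype=np.float64)
        constant = np.allclose(values, values[0])
        for j in clusters:
            indicator = (assignment == j).astype(float)
            if constant:
                rows.append(
                    {"outcome": outcome, "cluster": j, "tau": np.nan, "p_raw": np.nan,
                     "n": assignment.size, "m_tests": m, "significant_bonferroni": False,
                     "note": "constant outcome; tau undefined"}
                )
                continue
            res = stats.kendalltau(indicator, values)
            rows.append(
                {"outcome": outcome, "cluster": j, "tau": float(res.statistic),
                 "p_raw": float(res.pvalue), "n": assignment.size, "m_tests": m,
                 "significant_bonferroni": bool(res.pvalue < alpha / m), "note": ""}
            )
    return pd.DataFrame(rows)


def build_partition_comparison_prompt(
    texts: dict[str, list[str]],
    assignment_a,
    assignment_b,
    fields: tuple[str, ...] = ("diagnosis", "operation"),
    blind: bool = True,
    names: tuple[str, str] = ("Partition 1", "Partition 2"),
) -> str:
    """Prompt asking a text model to summarise the differences between
    two partitions of the same rows.

    With ``blind=True`` (the default) the partitions are presented only
    as "Partition 1"/"Partition 2" with no provenance, so the model
    cannot tell which is algorithmic and which is expert-defined.
    """
    assignment_a = np.asarray(assignment_a)
    assignment_b = np.asarray(assignment_b)
    if assignment_a.size != assignment_b.size:
        raise ValueError("partitions must cover the same rows")
    if blind:
        names = ("Partition 1", "Partition 2")
    header = (
        "Two alternative groupings of the same patients are listed below. "
        "Please summarise and explain the differences between the two "
        "partitions in terms of the clinical content of their groups."
    )
    sections = [header]
    for name, assignment in zip(names, (assignment_a, assignment_b)):
        prompt = build_label_prompt(texts, assignment, fields=fields)
        sections.append(f"{name}:\n{prompt.body}")
    return "\n\n########\n\n".join(sections)
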