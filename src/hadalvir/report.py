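"""Summary percentages across stage outputs.

The final reporting stage rolls stage outputs into the headline fractions
a virome survey reports: the share of vOTUs assigned a quality tier, the
share flagged transcriptionally active, the classified (family-level)
share, the host-linked share, and genus counts with and without
singletons.
"""

from __future__ import annotations

from typing import Mapping, Optional

import pandas as pd


def percent(numerator: int, denominator: int) -> int:
    """Nearest-integer percentage of a count pair."""
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if numerator < 0 or numerator > denominator:
        raise ValueError("numerator must be within [0, denominator]")
    return int(round(100.0 * numerator / denominator))


def summarize(
    tiers: Optional[pd.DataFrame] = None,
    activity: Optional[pd.DataFrame] = None,
    family_calls: Optional[pd.DataFrame] = None,
    predictions: Optional[pd.DataFrame] = None,
    votus: Optional[pd.DataFrame] = None,
    genera: Optional[pd.DataFrame] = None,
    triage: Optional[pd.DataFrame] = None,
) -> pd.DataFrame:
    """Aggregate stage outputs into named count/percentage summaries."""
    rows = []

    def add(name, numerator, denominator):
        rows.append({"summary": name, "numerator": int(numerator),
                     "denominator": int(denominator),
                     "percent": percent(int(numerator), int(denominator))})

    if triage is not None and len(triage):
        add("triage_retained", int(triage["retained"].sum()), len(triage))
    if tiers is not None and len(tiers):
        tiered = int((tiers["tier"] != "undetermined").sum())
        add("votus_with_quality_tier", tiered, len(tiers))
        add("votus_undetermined", len(tiers) - tiered, len(tiers))
        for tier in ("complete", "high", "medium", "low"):
            add(f"votus_{tier}", int((tiers["tier"] == tier).sum()),
                len(tiers))
    if activity is not None and len(activity):
        add("votus_transcriptionally_active", int(activity["active"].sum()),
            len(activity))
    if family_calls is not None and len(family_calls):
        classified = int((family_calls["family"] != "unclassified").sum())
        add("votus_classified_family", classified, len(family_calls))
    if predictions is not None and votus is not None and len(votus):
        n_votus = votus["votu_id"].nunique()
        linked = (predictions.loc[predictions["high_confidence"] == 1,
                                  "virus_id"].nunique()
                  if len(predictions) else 0)
        add("votus_host_linked", linked, n_votus)
    if genera is not None and len(genera):
        sizes = genera.groupby("cluster_id").size()
        add("genera_multimember", int((sizes > 1).sum()), len(sizes))
    return pd.DataFrame(rows, columns=["summary", "numerator", "denominator",
                                       "percent"])
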