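"""Outcome-frequency pooling across randomized trials.

Counts how many trials report each outcome, applies the core-outcome frequency
filter (keep outcomes reported in strictly more than a threshold percentage of
trials, 6% by default), and merges frequency-retained outcomes with candidates
proposed by other evidence sources (core-outcome-set studies, guidelines,
regulatory documents), tracking provenance for each candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from ._round import round_half_up

__all__ = [
    "ExtractionRecord",
    "frequency_filter",
    "merge_candidates",
    "normalize_name",
    "tally_outcomes",
]


class ValidationError(ValueError):
    pass


def normalize_name(name: str, synonym_map: Mapping[str, str] | None = None) -> str:
    """Trim/case-fold an outcome name, then apply an optional synonym map.

    Matching is exact after normalization; synonym resolution beyond the
    user-supplied map is deliberately out of scope.
    """
    key = " ".join(name.strip().split()).casefold()
    if synonym_map:
        folded = {" ".join(k.strip().split()).casefold(): v for k, v in synonym_map.items()}
        key = folded.get(key, key)
    return key


@dataclass(frozen=True)
class ExtractionRecord:
    """One trial's identifier and the set of (outcome, domain) pairs it reports."""

    trial_id: str
    outcomes: frozenset[tuple[str, str]]  # (outcome_name, evaluation_domain)

    @classmethod
    def from_pairs(
        cls, trial_id: str, pairs: Iterable[tuple[str, str]],
        synonym_map: Mapping[str, str] | None = None,
    ) -> "ExtractionRecord":
        cleaned = set()
        for name, domain in pairs:
            if not str(name).strip():
                raise ValidationError(f"trial {trial_id!r}: empty outcome name")
            cleaned.add((normalize_name(str(name), synonym_map), str(domain).strip()))
        return cls(str(trial_id), frozenset(cleaned))


def tally_outcomes(records: Sequence[ExtractionRecord]) -> pd.DataFrame:
    """Per-outcome trial counts and reporting frequencies.

    Each trial contributes at most once per outcome (set semantics).  The
    returned frame has columns ``outcome``, ``domain``, ``count``,
    ``frequency_percent`` (percent of trials, 2 decimals) sorted by count
    descending then name.  Conflicting domain labels for one outcome name
    raise, listing both.
    """
    if not records:
        raise ValidationError("no extraction records supplied")
    seen_ids = [r.trial_id for r in records]
    if len(set(seen_ids)) != len(seen_ids):
        dup = sorted({t for t in seen_ids if seen_ids.count(t) > 1})
        raise ValidationError(f"duplicate trial ids: {dup}")

    counts: dict[str, int] = {}
    domains: dict[str, str] = {}
    for rec in records:
        for name, domain in rec.outcomes:
            counts[name] = counts.get(name, 0) + 1
            if name in domains and domains[name] != domain:
                raise ValidationError(
                    f"outcome {name!r} assigned to both {domains[name]!r} and {domain!r}"
                )
            domains[name] = domain
    total = len(records)
    df = pd.DataFrame(
        {
            "outcome": list(counts),
            "domain": [domains[o] for o in counts],
            "count": list(counts.values()),
        }
    )
    df["frequency_percent"] = [round_half_up(100.0 * c / total, 2) for c in df["count"]]
    return df.sort_values(["count", "outcome"], ascending=[False, True]).reset_index(
        drop=True
    )


def frequency_filter(
    tally: pd.DataFrame, total_trials: int, threshold_percent: float = 6.0,
    strict: bool = True,
) -> pd.DataFrame:
    """Apply the core-outcome reporting-frequency filter.

    Outcomes reported in strictly more than ``threshold_percent`` of
    ``total_trials`` are retained ("more than 6%" reads as an open interval;
    set ``strict=False`` for >=).  Returns the tally with ``frequency_percent``
    recomputed against ``total_trials`` and a boolean ``retained`` column.
    """
    if total_trials <= 0:
        raise ValidationError("total_trials must be positive")
    if not (0 <= threshold_percent <= 100):
        raise ValidationError("threshold_percent must be in [0, 100]")
    out = tally.copy()
    freq = 100.0 * out["count"] / total_trials
    out["frequency_percent"] = [round_half_up(f, 2) for f in freq]
    out["retained"] = (freq > threshold_percent) if strict else (freq >= threshold_percent)
    return out


def merge_candidates(
    sources: Sequence[tuple[str, Iterable[tuple[str, str]]]],
    tally_core: pd.DataFrame | None = None,
    synonym_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Union candidate outcomes from evidence sources with the frequency-core set.

    ``sources`` is a list of ``(source_tag, [(outcome, domain), ...])``; the
    retained rows of a ``frequency_filter`` result join under the tag
    ``RCT_frequency``.  Each candidate is annotated with every source that
    proposed it; ordering is deterministic by (domain, name).  Conflicting
    domain labels raise.
    """
    tags = [t for t, _ in sources]
    if len(set(tags)) != len(tags):
        raise ValidationError("source tags must be unique")

    provenance: dict[str, set[str]] = {}
    domains: dict[str, str] = {}

    def _add(name: str, domain: str, tag: str) -> None:
        key = normalize_name(name, synonym_map)
        domain = str(domain).strip()
        if key in domains and domains[key] != domain:
            raise ValidationError(
                f"outcome {key!r} assigned to both {domains[key]!r} and {domain!r}"
            )
        domains[key] = domain
        provenance.setdefault(key, set()).add(tag)

    for tag, pairs in sources:
        for name, domain in pairs:
            _add(name, domain, tag)
    if tally_core is not None:
        core = tally_core[tally_core["retained"]] if "retained" in tally_core else tally_core
        for _, row in core.iterrows():
            _add(row["outcome"], row["domain"], "RCT_frequency")

    rows = [
        {
            "outcome": name,
            "domain": domains[name],
            "provenance": ",".join(sorted(provenance[name])),
            "included": True,
        }
        for name in provenance
    ]
    return (
        pd.DataFrame(rows, columns=["outcome", "domain", "provenance", "included"])
        .sort_values(["domain", "outcome"])
        .reset_index(drop=True)
    )
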