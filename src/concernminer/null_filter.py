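"""Meaningless-response filtering.

Open-ended survey fields attract a large share of contentless answers ("No",
"N/A", "nothing to add"). These convey no health information, so the whole
response is removed before any semantic analysis — entire-response removal,
deliberately distinct from a stop list, which would delete common words from
otherwise meaningful responses. Classification is exact match of the
normalized response against a bank of null patterns, which biases errors
toward keeping a response: any response not literally in the bank survives.

Participants whose only response is meaningless are treated downstream as
non-responders to the open-ended question.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

from ._util import substream

__all__ = [
    "normalize_pattern",
    "NullPatternSet",
    "default_patterns",
    "classify_meaningful",
    "split_responses",
    "audit_sample",
]

_STRIP = re.compile(r"[^a-z\s]+")
_WS = re.compile(r"\s+")


def normalize_pattern(text: str) -> str:
    """Lowercase, strip punctuation/digits, collapse whitespace, trim."""
    cleaned = _STRIP.sub("", text.lower())
    return _WS.sub(" ", cleaned).strip()


@dataclass
class NullPatternSet:
    """Deduplicated normalized patterns whose exact match means 'meaningless'."""

    patterns: frozenset[str]
    provenance: str = "user-supplied"

    def __post_init__(self):
        normalized = {normalize_pattern(p) for p in self.patterns}
        normalized.discard("")
        object.__setattr__(self, "patterns", frozenset(normalized))

    def __len__(self) -> int:
        return len(self.patterns)

    def __contains__(self, normalized: str) -> bool:
        return normalized in self.patterns

    def union(self, other: "NullPatternSet") -> "NullPatternSet":
        return NullPatternSet(self.patterns | other.patterns, provenance="merged")

    @classmethod
    def from_file(cls, path, provenance: str = "user-supplied") -> "NullPatternSet":
        """One pattern per line; '#' starts a comment; normalized on load."""
        lines = Path(path).read_text(encoding="utf-8").splitlines()
        pats = {ln for ln in (s.split("#", 1)[0] for s in lines) if ln.strip()}
        return cls(frozenset(pats), provenance=provenance)


def default_patterns() -> NullPatternSet:
    """The shipped fixture bank of common contentless responses."""
    with resources.as_file(
        resources.files("concernminer") / "data" / "null_patterns.txt"
    ) as p:
        return NullPatternSet.from_file(p, provenance="fixture")


def classify_meaningful(text: str, patterns: NullPatternSet) -> bool:
    """True iff the response conveys information: normalized form is nonempty
    and not an exact member of the pattern bank."""
    if len(patterns) == 0:
        raise ValueError("pattern set is empty")
    norm = normalize_pattern(text)
    return norm != "" and norm not in patterns


def split_responses(
    responses: pd.DataFrame,
    patterns: NullPatternSet,
    overrides: dict[str, bool] | None = None,
    text_col: str = "text",
    id_col: str = "response_id",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Partition a response table into (meaningful, meaningless).

    `overrides` maps response id -> forced meaningful flag, modelling human
    reclassification applied after the automatic pass.
    """
    flags = responses[text_col].map(lambda t: classify_meaningful(str(t), patterns))
    if overrides:
        forced = responses[id_col].map(overrides.get)
        flags = flags.where(forced.isna(), forced).astype(bool)
    meaningful = responses[flags].copy()
    meaningless = responses[~flags].copy()
    return meaningful, meaningless


def audit_sample(
    classified: pd.DataFrame, n: int, seed: int, id_col: str = "response_id"
) -> pd.DataFrame:
    """Seeded uniform sample without replacement for manual review.

    Returns the sampled rows (original order randomized) ready to write as a
    review sheet; the classic protocol reviews 250 responses classified
    meaningful to estimate the false-meaningful rate.
    """
    if n > len(classified):
        raise ValueError(f"cannot sample {n} from {len(classified)} responses")
    rng = substream(seed, "audit_sample")
    rows = rng.choice(len(classified), size=n, replace=False)
    sample = classified.iloc[rows].copy()
    sample["review_label"] = ""
    return sample


def filter_report(n_meaningful: int, n_meaningless: int) -> dict:
    total = n_meaningful + n_meaningless
    if total == 0:
        warnings.warn("no responses to filter")
    return {
        "n_responses": total,
        "n_meaningful": n_meaningful,
        "n_meaningless": n_meaningless,
    }
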