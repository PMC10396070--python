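"""End-to-end analysis pipeline: text -> tokens -> annotation -> metrics."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .annotator import (
    CUAnnotation,
    DEFAULT_PRONOUNS,
    match_content_units,
    normalize,
)
from .dictionary import CUDictionary
from .metrics import SampleMetrics, compute_sample_metrics
from .tokenizer import Conventions, TokenizedSample, tokenize

log = logging.getLogger("cutext")


@dataclass
class SampleResult:
    sample: TokenizedSample
    annotation: CUAnnotation
    metrics: SampleMetrics


def analyze_text(
    text: str,
    dictionary: CUDictionary,
    *,
    sample_id: str = "",
    group: str = "",
    modality: str = "",
    conventions: Conventions | None = None,
    pronoun_set: frozenset[str] = DEFAULT_PRONOUNS,
    pos_overrides: Mapping[tuple[int, int], str] | None = None,
) -> SampleResult:
    """Run the full scoring pipeline on one raw sample text."""
    sample = tokenize(
        text, conventions, sample_id=sample_id, group=group, modality=modality
    )
    tokens = normalize(sample, pos_overrides)
    annotation = match_content_units(
        tokens, dictionary, sample_id=sample_id, pronoun_set=pronoun_set
    )
    return SampleResult(sample, annotation, compute_sample_metrics(annotation, sample))


def analyze_table(
    transcripts: pd.DataFrame,
    dictionary: CUDictionary,
    *,
    conventions: Conventions | None = None,
    pronoun_set: frozenset[str] = DEFAULT_PRONOUNS,
    overrides_by_sample: Mapping[str, Mapping[tuple[int, int], str]] | None = None,
) -> list[SampleResult]:
    """Analyze a transcript table (columns sample_id, group, modality, text)."""
    required = {"sample_id", "group", "modality", "text"}
    if not required <= set(transcripts.columns):
        raise ValueError(f"transcript table must have columns {sorted(required)}")
    results = []
    for row in transcripts.itertuples(index=False):
        sid = str(row.sample_id)
        results.append(
            analyze_text(
                str(row.text),
                dictionary,
                sample_id=sid,
                group=str(row.group),
                modality=str(row.modality),
                conventions=conventions,
                pronoun_set=pronoun_set,
                pos_overrides=(overrides_by_sample or {}).get(sid),
            )
        )
    return results


def read_transcripts(path: str | Path) -> pd.DataFrame:
    """Read transcripts from a CSV file or a directory of UTF-8 .txt files."""
    path = Path(path)
    if path.is_dir():
        rows = []
        for f in sorted(path.glob("*.txt")):
            try:
                text = f.read_text(encoding="utf-8")
            except (OSError, UnicodeDecodeError) as exc:
                log.error("skipping unreadable file %s: %s", f, exc)
                continue
            rows.append(
                {"sample_id": f.stem, "group": "", "modality": "", "text": text}
            )
        if not rows:
            raise ValueError(f"no readable .txt files in {path}")
        return pd.DataFrame(rows)
    # output files carry leading '#' provenance lines (seed, preset)
    skip = 0
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if line.startswith("#"):
                skip += 1
            else:
                break
    df = pd.read_csv(path, dtype=str, keep_default_na=False, skiprows=skip)
    return df
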