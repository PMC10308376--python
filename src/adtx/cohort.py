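"""Neuropathology-based sample classification and low-expression filtering.

Samples are assigned to non-demented control, asymptomatic AD (AsymAD) or
AD from CERAD score (1-4, lower = more neuritic-plaque pathology), Braak
stage (0-6) and MMSE (dementia := MMSE < 24):

  control : CERAD 3-4, Braak 0-3, no dementia
  asymad  : CERAD 1-3, Braak 3-6, no dementia
  ad      : CERAD 1-2, Braak 3-6, dementia

The printed rules overlap at CERAD=3 / Braak=3 / no dementia (both the
control and AsymAD definitions match); a fixed, configurable precedence
(default ad -> asymad -> control, i.e. pathology-forward) resolves it and
the ambiguity is logged. A sample matching no rule is "unclassified".
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

LABELS = ("control", "asymad", "ad", "unclassified")
DEFAULT_PRECEDENCE = ("ad", "asymad", "control")


@dataclass(frozen=True)
class SampleMetadata:
    sample_id: str
    cerad: int
    braak: int
    mmse: int

    def __post_init__(self) -> None:
        if not 1 <= self.cerad <= 4:
            raise ValueError(f"{self.sample_id}: CERAD {self.cerad} outside 1-4")
        if not 0 <= self.braak <= 6:
            raise ValueError(f"{self.sample_id}: Braak {self.braak} outside 0-6")
        if not 0 <= self.mmse <= 30:
            raise ValueError(f"{self.sample_id}: MMSE {self.mmse} outside 0-30")


def _rule_matches(label: str, cerad: int, braak: int, dementia: bool) -> bool:
    if label == "control":
        return 3 <= cerad <= 4 and 0 <= braak <= 3 and not dementia
    if label == "asymad":
        return 1 <= cerad <= 3 and 3 <= braak <= 6 and not dementia
    if label == "ad":
        return 1 <= cerad <= 2 and 3 <= braak <= 6 and dementia
    raise ValueError(f"unknown rule {label!r}")


def classify_sample(
    m: SampleMetadata, precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
) -> str:
    """Diagnosis label for one sample; first matching rule in `precedence` wins."""
    dementia = m.mmse < 24
    matched = [lab for lab in precedence if _rule_matches(lab, m.cerad, m.braak, dementia)]
    if len(matched) > 1:
        logger.info(
            "sample %s matches rules %s; resolved to %s by precedence",
            m.sample_id, matched, matched[0],
        )
    return matched[0] if matched else "unclassified"


def classify_table(
    metadata: pd.DataFrame, precedence: tuple[str, ...] = DEFAULT_PRECEDENCE
) -> pd.Series:
    """Classify every row of a metadata table (sample_id, cerad, braak, mmse).

    Returns a Series of labels indexed by sample_id.
    """
    labels = {}
    for row in metadata.itertuples(index=False):
        m = SampleMetadata(str(row.sample_id), int(row.cerad), int(row.braak), int(row.mmse))
        labels[m.sample_id] = classify_sample(m, precedence)
    return pd.Series(labels, name="label").rename_axis("sample_id")


def filter_low_expression(
    x: pd.DataFrame, tpm_min: float = 0.1, frac_min: float = 0.05
) -> pd.DataFrame:
    """Drop rows not exceeding `tpm_min` TPM in at least ceil(frac_min * n) samples.

    "No less than 5% of all samples" is read with a ceiling on the sample
    count, applied jointly over all samples (not per group). Idempotent;
    preserves row order. An empty result is a warning, not an error.
    """
    if x.shape[1] == 0:
        raise ValueError("expression matrix has no samples")
    need = math.ceil(frac_min * x.shape[1])
    keep = (x.to_numpy() > tpm_min).sum(axis=1) >= need
    out = x.loc[keep]
    logger.info("expression filter kept %d/%d rows (>%g TPM in >=%d samples)",
                out.shape[0], x.shape[0], tpm_min, need)
    if out.empty:
        logger.warning("expression filter removed every row")
    return out


def group_samples(labels: pd.Series, group: str) -> list[str]:
    """Sample ids carrying a given diagnosis label."""
    if group not in LABELS:
        raise ValueError(f"unknown group label {group!r}")
    return list(labels.index[labels == group])
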