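"""Count-matrix container shared by the screen and expression stages.

A :class:`CountMatrix` wraps a features × samples :class:`pandas.DataFrame`
of non-negative counts (or non-negative reals once normalized) together with
a per-sample metadata table (arm, replicate, group). Raw and normalized
matrices are distinguished by an explicit flag so downstream stages can
insist on one or the other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError

SAMPLE_SHEET_COLUMNS = ("sample", "arm", "replicate", "group")


@dataclass
class CountMatrix:
    """Features × samples matrix with per-sample metadata.

    Parameters
    ----------
    values
        DataFrame indexed by feature id (shRNA or gene symbol) with one
        column per sample. Entries must be non-negative and finite.
    samples
        Per-sample metadata indexed by sample id, with columns ``arm``,
        ``replicate`` and ``group`` (any subset may be empty strings).
    normalized
        True once the matrix has been library-size normalized (e.g. CPM);
        raw integer matrices carry False.
    """

    values: pd.DataFrame
    samples: pd.DataFrame = field(default=None)  # type: ignore[assignment]
    normalized: bool = False

    def __post_init__(self) -> None:
        if self.samples is None:
            self.samples = pd.DataFrame(
                {"arm": "", "replicate": "", "group": ""},
                index=self.values.columns,
            )
        self.samples.index.name = "sample"
        self.values.index.name = "feature_id"
        self.validate()

    # -- contracts ---------------------------------------------------------
    def validate(self) -> None:
        vals = self.values.to_numpy()
        if vals.size and (not np.isfinite(vals).all() or (vals < 0).any()):
            raise ValidationError("count matrix contains negative or non-finite entries")
        if self.values.index.has_duplicates:
            raise ValidationError("duplicate feature ids in count matrix")
        if self.values.columns.has_duplicates:
            raise ValidationError("duplicate sample ids in count matrix")
        missing = set(self.values.columns) - set(self.samples.index)
        if missing:
            raise ValidationError(f"samples missing from sample sheet: {sorted(missing)}")

    # -- convenience -------------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def samples_in_arm(self, arm: str) -> list[str]:
        sel = self.samples.index[self.samples["arm"] == arm]
        return [s for s in self.values.columns if s in set(sel)]

    def samples_in_group(self, group: str) -> list[str]:
        sel = self.samples.index[self.samples["group"] == group]
        return [s for s in self.values.columns if s in set(sel)]

    def require_samples(self, sample_ids) -> None:
        missing = [s for s in sample_ids if s not in self.values.columns]
        if missing:
            raise ValidationError(f"sample ids not in matrix: {missing}")

    # -- I/O ---------------------------------------------------------------
    def to_tsv(self, counts_path: str | Path, sample_sheet_path: str | Path | None = None) -> None:
        self.values.to_csv(counts_path, sep="\t")
        if sample_sheet_path is not None:
            self.samples.to_csv(sample_sheet_path, sep="\t")

    @classmethod
    def from_tsv(
        cls,
        counts_path: str | Path,
        sample_sheet_path: str | Path | None = None,
        normalized: bool = False,
    ) -> "CountMatrix":
        values = pd.read_csv(counts_path, sep="\t", index_col=0)
        samples = None
        if sample_sheet_path is not None:
            samples = pd.read_csv(sample_sheet_path, sep="\t", index_col=0, dtype=str)
            samples = samples.fillna("")
        return cls(values=values, samples=samples, normalized=normalized)
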