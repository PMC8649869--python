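"""Barcode quantification: FASTQ reads → shRNA × sample count matrix.

Reads are assigned to library barcodes either at a fixed offset or by
anchoring on the 5' flank sequence. Matching tolerates at most one
substitution (Hamming distance on the barcode segment); reads equidistant
from two library barcodes are never counted. 'N' never matches any base.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO

from .errors import ParameterError, PipelineIOError, ValidationError
from .matrix import CountMatrix
from .synthetic import ShRNALibrary

NO_CALL = None


@dataclass
class MatchPolicy:
    """How to locate and match the barcode segment of a read.

    Exactly one of ``offset`` (fixed 0-based start) or ``flank5``
    (anchor sequence located allowing <= 1 substitution) must be set.
    ``max_mismatch`` is the Hamming tolerance on the barcode itself (0 or 1).
    """

    max_mismatch: int = 1
    offset: int | None = None
    flank5: str | None = None

    def __post_init__(self) -> None:
        if self.max_mismatch not in (0, 1):
            raise ParameterError("max_mismatch must be 0 or 1")
        if (self.offset is None) == (self.flank5 is None):
            raise ParameterError("set exactly one of offset or flank5")
        if self.offset is not None and self.offset < 0:
            raise ParameterError("offset must be >= 0")
        if self.flank5 is not None and not self.flank5:
            raise ParameterError("flank5 must be non-empty")


def _hamming(a: str, b: str) -> int:
    return sum(x != y for x, y in zip(a, b))


def _locate_flank(read: str, flank: str) -> int | None:
    """Start of the leftmost window matching ``flank`` with <= 1 substitution.

    Leftmost-admissible (rather than exact-anywhere-first) semantics: a
    single error inside the true anchor must not let a chance exact
    occurrence further into the read capture the barcode position.
    """
    k = len(flank)
    for i in range(len(read) - k + 1):
        if _hamming(read[i : i + k], flank) <= 1:
            return i
    return None


def extract_barcode(read: str, policy: MatchPolicy, barcode_length: int) -> str | None:
    """Extract the barcode-length segment of a read, or return None (no-call).

    Offset mode takes the substring at the fixed position; anchored mode
    locates the 5' flank (<= 1 substitution) and takes the following
    ``barcode_length`` bases. Reads too short for either mode are no-calls.
    """
    read = read.upper()
    if policy.offset is not None:
        start = policy.offset
    else:
        pos = _locate_flank(read, policy.flank5.upper())
        if pos is None:
            return NO_CALL
        start = pos + len(policy.flank5)
    if len(read) < start + barcode_length:
        return NO_CALL
    return read[start : start + barcode_length]


def _build_matcher(library: ShRNALibrary, max_mismatch: int):
    """Return barcode -> row-index resolver honouring the mismatch policy."""
    exact = {r.barcode.upper(): i for i, r in enumerate(library.records)}

    def resolve(bc: str) -> int | None:
        hit = exact.get(bc)
        if hit is not None:
            return hit
        if max_mismatch == 0:
            return None
        # enumerate Hamming-1 neighbours; ambiguity (two hits) is a discard
        found: int | None = None
        for i, base in enumerate(bc):
            prefix, suffix = bc[:i], bc[i + 1 :]
            for sub in "ACGT":
                if sub == base:
                    continue
                hit = exact.get(prefix + sub + suffix)
                if hit is not None:
                    if found is not None and hit != found:
                        return None
                    found = hit
        return found

    return resolve


def count_barcodes(
    fastq_paths: dict[str, str | Path],
    library: ShRNALibrary,
    policy: MatchPolicy,
) -> tuple[CountMatrix, dict[str, int]]:
    """Tally reads per library barcode for each sample's FASTQ.

    Every read lands in exactly one matrix cell or in the per-sample discard
    tally, so assigned + discarded equals total reads. Returns the raw count
    matrix and the discard tally.
    """
    if len(set(fastq_paths)) != len(fastq_paths):
        raise ValidationError("duplicate sample names")
    resolve = _build_matcher(library, policy.max_mismatch)
    n_features = len(library)
    columns: dict[str, np.ndarray] = {}
    discards: dict[str, int] = {}
    for sample, path in fastq_paths.items():
        col = np.zeros(n_features, dtype=np.int64)
        dropped = 0
        path = Path(path)
        try:
            if path.suffix == ".gz":
                import gzip

                handle = gzip.open(path, "rt")
            else:
                handle = open(path)
            with handle:
                for rec_index, rec in enumerate(SeqIO.parse(handle, "fastq")):
                    bc = extract_barcode(str(rec.seq), policy, library.barcode_length)
                    row = resolve(bc) if bc is not None else None
                    if row is None:
                        dropped += 1
                    else:
                        col[row] += 1
        except (OSError, ValueError) as exc:
            raise PipelineIOError(f"failed reading {path} (record ~{locals().get('rec_index', 0)}): {exc}") from exc
        columns[sample] = col
        discards[sample] = dropped
    values = pd.DataFrame(columns, index=pd.Index(library.shrna_ids, name="feature_id"))
    return CountMatrix(values=values, normalized=False), discards


def cpm_normalize(counts: CountMatrix) -> CountMatrix:
    """Rescale every sample to one million total counts (CPM)."""
    totals = counts.values.sum(axis=0)
    zero = totals.index[totals == 0].tolist()
    if zero:
        raise ValidationError(f"all-zero samples cannot be CPM-normalized: {zero}")
    values = counts.values.astype(float) * (1e6 / totals)
    return CountMatrix(values=values, samples=counts.samples.copy(), normalized=True)
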