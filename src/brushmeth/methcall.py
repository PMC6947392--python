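"""From bisulfite amplicon FASTQ to a per-CpG methylation-ratio matrix.

The caller works on an in-silico C->T converted reference: reads are C->T
collapsed, assigned to the best (amplicon, offset) by ungapped sliding
comparison, and the ORIGINAL read base at each covered CpG is recorded as
the C/T call. CpG columns are excluded from the mismatch count so that a
methylated read is not penalised for its biology.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.lib.stride_tricks import sliding_window_view
from scipy import stats

from .fastqio import FastqRecord
from .panel import AmpliconPanel

_COMPLEMENT = bytes.maketrans(b"ACGT", b"TGCA")


@dataclass(frozen=True)
class AlignedRead:
    """A read assigned to one amplicon, with its per-CpG base calls."""

    read_id: str
    amplicon_id: str
    offset: int
    calls: dict[str, str]  # cpg_id -> observed base on the oriented read
    mean_quality: float
    mismatches: int
    reverse: bool = False


@dataclass
class MethylationMatrix:
    """Samples x CpGs methylation ratios with a coverage twin.

    ``ratios`` holds NaN where coverage (C+T calls) is below the caller's
    ``min_coverage``; ``coverage`` always holds the raw C+T count.
    """

    ratios: pd.DataFrame
    coverage: pd.DataFrame

    def __post_init__(self) -> None:
        if not self.ratios.index.equals(self.coverage.index) or not (
            self.ratios.columns.equals(self.coverage.columns)
        ):
            raise ValueError("ratios and coverage must share index and columns")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.ratios.index)

    @property
    def cpg_ids(self) -> list[str]:
        return list(self.ratios.columns)

    @classmethod
    def from_rows(cls, rows: list["MethylationMatrix"]) -> "MethylationMatrix":
        return cls(
            pd.concat([r.ratios for r in rows]),
            pd.concat([r.coverage for r in rows]),
        )

    def write_tsv(self, ratios_path: str | Path, coverage_path: str | Path) -> None:
        self.ratios.to_csv(ratios_path, sep="\t", na_rep="NA", index_label="sample_id")
        self.coverage.to_csv(coverage_path, sep="\t", index_label="sample_id")

    @classmethod
    def read_tsv(
        cls, ratios_path: str | Path, coverage_path: str | Path
    ) -> "MethylationMatrix":
        ratios = pd.read_csv(ratios_path, sep="\t", index_col="sample_id", na_values="NA")
        coverage = pd.read_csv(coverage_path, sep="\t", index_col="sample_id")
        return cls(ratios, coverage.astype(int))


# ---------------------------------------------------------------------------
# quality filtering
# ---------------------------------------------------------------------------

def quality_filter(
    reads: list[FastqRecord], q_threshold: float = 30.0
) -> tuple[list[FastqRecord], dict[str, int]]:
    """Keep reads with mean Phred strictly greater than ``q_threshold``.

    The threshold is on the per-read mean quality; a read at uniform Q30
    is discarded (strict inequality). Order is preserved.
    """
    kept = [r for r in reads if r.mean_quality > q_threshold]
    stats_ = {"input": len(reads), "kept": len(kept), "discarded": len(reads) - len(kept)}
    return kept, stats_


# ---------------------------------------------------------------------------
# reference conversion and alignment
# ---------------------------------------------------------------------------

def convert_reference(panel: AmpliconPanel) -> dict[str, str]:
    """In-silico bisulfite conversion of the reference: every C -> T.

    The CpG position map is the identity (conversion is a substitution),
    so downstream code keeps using the panel's original offsets.
    """
    return {amp.gene_name: amp.sequence.replace("C", "T") for amp in panel}


def _to_u8(seq: str) -> np.ndarray:
    return np.frombuffer(seq.encode(), dtype=np.uint8)


def reverse_complement(seq: str) -> str:
    return seq.encode().translate(_COMPLEMENT)[::-1].decode()


class PanelIndex:
    """Precomputed converted reference arrays and CpG masks for alignment."""

    def __init__(self, panel: AmpliconPanel):
        if len(panel) == 0:
            raise ValueError("panel is empty")
        self.panel = panel
        converted = convert_reference(panel)
        self.conv: dict[str, np.ndarray] = {g: _to_u8(s) for g, s in converted.items()}
        self.cpg_mask: dict[str, np.ndarray] = {}
        for amp in panel:
            mask = np.zeros(len(amp.sequence), dtype=bool)
            mask[list(amp.cpg_positions)] = True
            self.cpg_mask[amp.gene_name] = mask
        self._windows: dict[tuple[str, int], tuple[np.ndarray, np.ndarray]] = {}

    def windows(self, gene: str, read_len: int) -> tuple[np.ndarray, np.ndarray] | None:
        """(converted windows, CpG-column masks), both (n_offsets, read_len)."""
        key = (gene, read_len)
        if key not in self._windows:
            conv = self.conv[gene]
            if read_len > conv.size:
                self._windows[key] = None  # type: ignore[assignment]
            else:
                self._windows[key] = (
                    sliding_window_view(conv, read_len),
                    sliding_window_view(self.cpg_mask[gene], read_len),
                )
        return self._windows[key]


def assign_and_align(
    read: FastqRecord,
    panel: AmpliconPanel,
    max_mismatch_rate: float = 0.1,
    index: PanelIndex | None = None,
) -> AlignedRead | None:
    """Assign a read to the best (amplicon, offset) or return None.

    Both the read and its reverse complement are tried; the C->T collapsed
    read is compared ungapped against every window of every converted
    amplicon, CpG columns excluded from the mismatch count. A tie between
    two amplicons at the best score leaves the read unassigned.
    """
    idx = index if index is not None else PanelIndex(panel)
    rl = len(read.sequence)
    if rl == 0:
        return None

    candidates: list[tuple[int, str, int, bool]] = []  # (mism, gene, offset, reverse)
    best = np.inf
    for reverse, oriented in ((False, read.sequence), (True, reverse_complement(read.sequence))):
        collapsed = _to_u8(oriented.replace("C", "T"))
        for amp in idx.panel:
            win = idx.windows(amp.gene_name, rl)
            if win is None:
                continue
            ref_win, cpg_win = win
            mism = ((ref_win != collapsed) & ~cpg_win).sum(axis=1)
            o = int(mism.argmin())
            m = int(mism[o])
            if m < best:
                best = m
                candidates = [(m, amp.gene_name, o, reverse)]
            elif m == best:
                candidates.append((m, amp.gene_name, o, reverse))

    if not candidates or best > max_mismatch_rate * rl:
        return None
    genes = {c[1] for c in candidates}
    if len(genes) > 1:
        return None  # ambiguous between amplicons
    m, gene, offset, reverse = candidates[0]

    oriented = reverse_complement(read.sequence) if reverse else read.sequence
    amp = idx.panel.get(gene)
    calls = {
        cid: oriented[p - offset]
        for p, cid in zip(amp.cpg_positions, amp.cpg_ids)
        if offset <= p < offset + rl
    }
    return AlignedRead(
        read_id=read.id,
        amplicon_id=gene,
        offset=offset,
        calls=calls,
        mean_quality=read.mean_quality,
        mismatches=m,
        reverse=reverse,
    )


def align_reads(
    reads: list[FastqRecord],
    panel: AmpliconPanel,
    max_mismatch_rate: float = 0.1,
) -> tuple[list[AlignedRead], dict[str, int]]:
    """Assign a batch of reads; returns aligned reads and assignment counts."""
    idx = PanelIndex(panel)
    aligned: list[AlignedRead] = []
    unassigned = 0
    for read in reads:
        hit = assign_and_align(read, panel, max_mismatch_rate, index=idx)
        if hit is None:
            unassigned += 1
        else:
            aligned.append(hit)
    counts = {"input": len(reads), "assigned": len(aligned), "unassigned": unassigned}
    return aligned, counts


# ---------------------------------------------------------------------------
# methylation calling
# ---------------------------------------------------------------------------

def call_methylation(
    aligned: list[AlignedRead],
    panel: AmpliconPanel,
    min_coverage: int = 50,
    sample_id: str = "sample",
) -> MethylationMatrix:
    """One sample row of per-CpG ratios #C/(#C+#T) with coverage.

    Calls other than C/T (sequencing errors) are excluded from both the
    numerator and the denominator; CpGs whose C+T coverage falls below
    ``min_coverage`` are reported missing (NaN) but keep their coverage.
    """
    cpg_ids = list(panel.cpg_ids)
    c_counts = dict.fromkeys(cpg_ids, 0)
    t_counts = dict.fromkeys(cpg_ids, 0)
    if not aligned:
        warnings.warn(f"{sample_id}: zero aligned reads; all CpGs missing")
    for read in aligned:
        for cid, base in read.calls.items():
            if base == "C":
                c_counts[cid] += 1
            elif base == "T":
                t_counts[cid] += 1
    cov = np.array([c_counts[c] + t_counts[c] for c in cpg_ids], dtype=int)
    with np.errstate(invalid="ignore", divide="ignore"):
        ratio = np.array(
            [c_counts[c] for c in cpg_ids], dtype=float
        ) / np.where(cov > 0, cov, 1)
    ratio = np.where(cov >= min_coverage, ratio, np.nan)
    return MethylationMatrix(
        ratios=pd.DataFrame([ratio], index=[sample_id], columns=cpg_ids),
        coverage=pd.DataFrame([cov], index=[sample_id], columns=cpg_ids),
    )


# ---------------------------------------------------------------------------
# assay reliability (duplicate agreement)
# ---------------------------------------------------------------------------

def assay_reliability(values_a, values_b) -> tuple[float, float]:
    """OLS of duplicate-2 on duplicate-1 values; returns (R^2, slope p).

    Accepts paired 1-D vectors (e.g. per-sample scores of duplicate runs)
    or two MethylationMatrix objects, in which case each sample's mean
    ratio over CpGs observed in both runs is used.
    """
    if isinstance(values_a, MethylationMatrix):
        a = values_a.ratios.mean(axis=1, skipna=True).to_numpy()
        b = values_b.ratios.mean(axis=1, skipna=True).to_numpy()
    else:
        a = np.asarray(values_a, dtype=float)
        b = np.asarray(values_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("duplicate value vectors must be paired 1-D arrays")
    if a.size < 3:
        raise ValueError("need at least 3 duplicate pairs for regression")
    if np.std(a) == 0:
        raise ValueError("degenerate duplicate-1 values (zero variance)")
    fit = stats.linregress(a, b)
    return float(fit.rvalue**2), float(fit.pvalue)
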