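"""Expression matrix container and group-level percentile summaries.

The percentile convention used throughout the package is linear
interpolation between closest order statistics (rank ``1 + (n-1)p/100``),
i.e. numpy's default; tertile cuts, the 75th/90th percentile selection
statistics and the summary tables below all share it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

GROUP_KINDS = ("cancer", "healthy", "validation")


def percentile(values: Sequence[float] | np.ndarray, p: float) -> float:
    """Linear-interpolation percentile at rank ``1 + (n-1)p/100``."""
    arr = np.asarray(values, dtype=float)
    if arr.size == 0:
        raise ValueError("percentile of empty values is undefined")
    if not 0 <= p <= 100:
        raise ValueError(f"percentile p={p} outside [0, 100]")
    return float(np.percentile(arr, p))


class ExpressionMatrix:
    """Transcripts x samples TPM matrix with a sample design.

    ``metadata`` carries one row per sample with columns ``sample_id``,
    ``group``, ``group_kind`` (cancer | healthy | validation) and optional
    ``matched_tissue`` naming the healthy group matched to a cancer group.
    """

    def __init__(self, tpm: pd.DataFrame, metadata: pd.DataFrame):
        if (tpm.values < 0).any():
            raise ValueError("TPM matrix contains negative values")
        meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
        missing = [s for s in tpm.columns if s not in meta.index]
        if missing:
            raise ValueError(f"samples without metadata: {missing[:5]}")
        bad_kind = set(meta["group_kind"]) - set(GROUP_KINDS)
        if bad_kind:
            raise ValueError(f"unknown group_kind values: {sorted(bad_kind)}")
        if "matched_tissue" in meta.columns:
            healthy = set(meta.loc[meta["group_kind"] == "healthy", "group"])
            matched = set(meta["matched_tissue"].dropna()) - {""}
            unknown = matched - healthy
            if unknown:
                raise ValueError(f"matched_tissue names unknown healthy groups: {sorted(unknown)}")
        self.tpm = tpm
        self.metadata = meta.loc[list(tpm.columns)]

    # -- construction -------------------------------------------------------
    @classmethod
    def from_tsv(cls, matrix_path: str | Path, metadata_path: str | Path) -> "ExpressionMatrix":
        tpm = pd.read_csv(matrix_path, sep="\t", index_col=0)
        meta = pd.read_csv(metadata_path, sep="\t")
        return cls(tpm, meta)

    @classmethod
    def from_quant_dir(cls, quant_dir: str | Path, metadata: pd.DataFrame) -> "ExpressionMatrix":
        """Join per-sample two-column (transcript_id, TPM) quant TSVs."""
        quant_dir = Path(quant_dir)
        cols = {}
        for path in sorted(quant_dir.glob("*.tsv")):
            s = pd.read_csv(path, sep="\t", index_col=0).iloc[:, 0]
            cols[path.stem] = s
        if not cols:
            raise ValueError(f"no quant TSVs found in {quant_dir}")
        return cls(pd.DataFrame(cols), metadata)

    def to_tsv(self, matrix_path: str | Path, metadata_path: str | Path) -> None:
        self.tpm.to_csv(matrix_path, sep="\t", index_label="transcript_id")
        self.metadata.to_csv(metadata_path, sep="\t", index_label="sample_id")

    # -- design accessors ----------------------------------------------------
    @property
    def transcript_ids(self) -> list[str]:
        return list(self.tpm.index)

    def groups(self, kind: str | None = None) -> list[str]:
        meta = self.metadata
        if kind is not None:
            meta = meta[meta["group_kind"] == kind]
        return sorted(meta["group"].unique())

    @property
    def cancer_groups(self) -> list[str]:
        return self.groups("cancer")

    @property
    def healthy_groups(self) -> list[str]:
        return self.groups("healthy")

    @property
    def validation_groups(self) -> list[str]:
        return self.groups("validation")

    def samples_of(self, group: str) -> list[str]:
        return list(self.metadata.index[self.metadata["group"] == group])

    def matched_tissue(self, cancer_group: str) -> str | None:
        if "matched_tissue" not in self.metadata.columns:
            return None
        vals = self.metadata.loc[self.metadata["group"] == cancer_group, "matched_tissue"]
        vals = vals.dropna()
        vals = vals[vals != ""]
        return None if vals.empty else str(vals.iloc[0])

    def group_values(self, group: str) -> pd.DataFrame:
        samples = self.samples_of(group)
        if not samples:
            raise ValueError(f"group {group!r} has zero samples")
        return self.tpm[samples]

    def healthy_values(self) -> pd.DataFrame:
        """All healthy samples pooled (criterion-2 denominator)."""
        samples = list(self.metadata.index[self.metadata["group_kind"] == "healthy"])
        return self.tpm[samples]


@dataclass
class GroupSummary:
    """Per transcript x group percentile summaries."""

    median: pd.DataFrame
    p75: pd.DataFrame
    p90: pd.DataFrame
    frac_above: pd.DataFrame  # fraction of group samples with TPM > threshold
    threshold: float
    max_cancer_p75: pd.Series  # upper-quartile TPM in the highest cancer type


def summarize_groups(
    matrix: ExpressionMatrix,
    threshold: float = 1.0,
    kinds: Iterable[str] = ("cancer", "healthy"),
) -> GroupSummary:
    """Median / p75 / p90 and expressed-sample fraction per group.

    Also reports the cross-cancer maximum of the 75th percentile — the
    "upper quartile TPM in the cancer type with highest expression" used as
    the per-transcript expression level in composition summaries.
    """
    groups = [g for k in kinds for g in matrix.groups(k)]
    med, p75, p90, frac = {}, {}, {}, {}
    for g in groups:
        vals = matrix.group_values(g).values
        med[g] = np.percentile(vals, 50, axis=1)
        p75[g] = np.percentile(vals, 75, axis=1)
        p90[g] = np.percentile(vals, 90, axis=1)
        frac[g] = (vals > threshold).mean(axis=1)
    idx = matrix.tpm.index
    median_df = pd.DataFrame(med, index=idx)
    p75_df = pd.DataFrame(p75, index=idx)
    p90_df = pd.DataFrame(p90, index=idx)
    frac_df = pd.DataFrame(frac, index=idx)
    cancer = [g for g in matrix.cancer_groups if g in p75_df.columns]
    max_c = p75_df[cancer].max(axis=1) if cancer else pd.Series(0.0, index=idx)
    return GroupSummary(median_df, p75_df, p90_df, frac_df, threshold, max_c)
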