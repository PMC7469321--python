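"""Bisulfite read-count quantification, QC filtering, and coordinates.

Turns per-sample Bismark-coverage-style count files into a QC-filtered
samples x CpG methylation matrix, keeping GRCh37 and TSS-relative
coordinate bookkeeping for the assayed promoter panel.

QC rules: samples with bisulfite conversion rate below 0.98 are dropped,
then sites whose mean coverage across the retained samples is below 20x
are dropped (boundaries are kept in both cases). Filtering is applied in
that order and every exclusion is logged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

CONVERSION_THRESHOLD = 0.98
MIN_MEAN_COVERAGE = 20.0


@dataclass(frozen=True)
class CpGSite:
    """A genomic CpG locus with its TSS-relative offset."""

    chrom: str
    position: int  # 1-based GRCh37 coordinate
    strand: str
    tss_offset: int
    label: str


@dataclass
class MethylationMatrix:
    """Samples x CpG methylation percentages with a missingness mask.

    ``values`` holds percentages in [0, 100]; missing cells are NaN.
    ``coverage`` holds total read counts (0 where no data), or None when
    the matrix did not originate from read counts.
    """

    sample_ids: list[str]
    sites: list[CpGSite]
    values: np.ndarray
    coverage: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.sites)):
            raise ValueError("values shape inconsistent with sample/site lists")
        finite = self.values[np.isfinite(self.values)]
        if finite.size and (finite.min() < 0 or finite.max() > 100):
            raise ValueError("methylation percentages must lie in [0, 100]")
        if self.coverage is not None:
            self.coverage = np.asarray(self.coverage, dtype=float)
            if self.coverage.shape != self.values.shape:
                raise ValueError("coverage shape inconsistent with values")

    @property
    def site_labels(self) -> list[str]:
        return [s.label for s in self.sites]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.site_labels,
        )

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


@dataclass
class QCReport:
    """Machine-readable record of what QC removed and why."""

    excluded_samples: list[tuple[str, str]] = field(default_factory=list)
    excluded_sites: list[tuple[str, str]] = field(default_factory=list)
    ignored_records: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [("sample", sid, reason) for sid, reason in self.excluded_samples]
        rows += [("site", lab, reason) for lab, reason in self.excluded_sites]
        rows += [("warning", "", w) for w in self.warnings]
        rows += [("ignored_records", str(self.ignored_records), "off-panel or extra records")]
        return pd.DataFrame(rows, columns=["kind", "id", "detail"])

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def tss_offset(position: int, tss_coordinate: int, strand: str) -> int:
    """Signed bp offset of ``position`` relative to the TSS.

    On the reverse strand upstream positions have larger coordinates, so
    the offset is ``tss - position``; on the forward strand it is
    ``position - tss``.
    """
    if position <= 0 or tss_coordinate <= 0:
        raise ValueError("coordinates must be positive")
    if strand == "-":
        return tss_coordinate - position
    if strand == "+":
        return position - tss_coordinate
    raise ValueError(f"unknown strand code {strand!r}")


def methylation_percent(count_methylated: int, count_unmethylated: int) -> float:
    """Percent methylation 100*M/(M+U); NaN when there are no reads."""
    if count_methylated < 0 or count_unmethylated < 0:
        raise ValueError("read counts must be non-negative")
    total = count_methylated + count_unmethylated
    if total == 0:
        return math.nan
    return 100.0 * count_methylated / total


def nppa_panel() -> list[CpGSite]:
    """The bundled nine-site NPPA promoter panel (GRCh37, reverse strand)."""
    from . import datasets

    return [
        CpGSite(
            chrom=datasets.NPPA_CHROM,
            position=pos,
            strand=datasets.NPPA_STRAND,
            tss_offset=tss_offset(pos, datasets.NPPA_TSS, datasets.NPPA_STRAND),
            label=label,
        )
        for label, pos in datasets.NPPA_SITE_POSITIONS
    ]


def filter_samples(
    manifest: pd.DataFrame,
    threshold: float = CONVERSION_THRESHOLD,
) -> tuple[list[str], QCReport]:
    """Keep samples whose bisulfite conversion rate is >= ``threshold``.

    ``manifest`` needs columns ``sample_id`` and ``conversion_rate``.
    Returns the retained sample ids plus a report listing each exclusion.
    """
    report = QCReport()
    if manifest.empty:
        report.warnings.append("empty manifest: no samples to retain")
        return [], report
    rates = manifest["conversion_rate"].to_numpy(dtype=float)
    if np.any((rates < 0) | (rates > 1)):
        raise ValueError("conversion rates must lie in [0, 1]")
    kept = []
    for sid, rate in zip(manifest["sample_id"], rates):
        if rate >= threshold:
            kept.append(str(sid))
        else:
            report.excluded_samples.append(
                (str(sid), f"conversion rate {rate:.4f} < {threshold:.2f}")
            )
    return kept, report


def filter_sites(
    coverage: np.ndarray,
    site_labels: list[str],
    min_mean_coverage: float = MIN_MEAN_COVERAGE,
) -> tuple[np.ndarray, QCReport]:
    """Keep sites with mean coverage >= ``min_mean_coverage`` across samples.

    Returns a boolean keep-mask over sites plus an exclusion report.
    """
    coverage = np.asarray(coverage, dtype=float)
    if np.any(coverage < 0):
        raise ValueError("coverage must be non-negative")
    report = QCReport()
    if coverage.shape[0] == 0:
        report.warnings.append("no samples: all sites dropped")
        return np.zeros(coverage.shape[1], dtype=bool), report
    means = coverage.mean(axis=0)
    keep = means >= min_mean_coverage
    for j, ok in enumerate(keep):
        if not ok:
            report.excluded_sites.append(
                (site_labels[j], f"mean coverage {means[j]:.2f} < {min_mean_coverage:g}")
            )
    return keep, report


def read_site_panel(path) -> tuple[list[CpGSite], int]:
    """Read a BED-like site panel with a YAML header giving the TSS.

    Header lines start with ``#`` and form a YAML document that must
    provide ``tss_coordinate``. Body columns: chrom, start (0-based),
    end, label, strand.
    """
    header_lines, body_lines = [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                header_lines.append(line.lstrip("#").rstrip("\n"))
            elif line.strip():
                body_lines.append(line.rstrip("\n"))
    meta = yaml.safe_load("\n".join(header_lines)) or {}
    if "tss_coordinate" not in meta:
        raise ValueError(f"panel {path} lacks a tss_coordinate header")
    tss = int(meta["tss_coordinate"])
    sites = []
    for ln in body_lines:
        chrom, start, end, label, strand = ln.split("\t")
        pos = int(start) + 1  # BED start is 0-based
        if pos != int(end):
            raise ValueError(f"panel row {label}: expected single-base interval")
        sites.append(
            CpGSite(chrom=chrom, position=pos, strand=strand,
                    tss_offset=tss_offset(pos, tss, strand), label=label)
        )
    return sites, tss


def write_site_panel(sites: list[CpGSite], tss_coordinate: int, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# tss_coordinate: {tss_coordinate}\n")
        for s in sites:
            fh.write(f"{s.chrom}\t{s.position - 1}\t{s.position}\t{s.label}\t{s.strand}\n")


def _parse_coverage_file(path, sample_id: str) -> dict[tuple[str, int], tuple[int, int]]:
    records: dict[tuple[str, int], tuple[int, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6:
                raise ValueError(
                    f"{path}:{lineno}: expected 6 tab-separated fields, got {len(parts)}"
                )
            chrom, start, _end, _pct, m_str, u_str = parts
            try:
                pos, m, u = int(start), int(m_str), int(u_str)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: malformed counts") from exc
            key = (chrom, pos)
            if key in records:
                raise ValueError(
                    f"{path}:{lineno}: duplicate record for sample {sample_id} at {chrom}:{pos}"
                )
            records[key] = (m, u)
    return records


def read_coverage_files(
    manifest: pd.DataFrame,
    panel: list[CpGSite],
    base_dir=None,
    conversion_threshold: float = CONVERSION_THRESHOLD,
    min_mean_coverage: float = MIN_MEAN_COVERAGE,
) -> tuple[MethylationMatrix, QCReport]:
    """Assemble a QC-filtered methylation matrix from coverage files.

    ``manifest`` columns: sample_id, file, conversion_rate. File paths are
    resolved against ``base_dir`` when given. Applies sample filtering,
    then site filtering, then percent conversion; records absent for a
    sample are masked, off-panel records are counted and ignored.
    """
    kept_ids, report = filter_samples(manifest, conversion_threshold)
    by_pos = {(s.chrom, s.position): j for j, s in enumerate(panel)}
    n, k = len(kept_ids), len(panel)
    meth_counts = np.zeros((n, k))
    totals = np.zeros((n, k))
    seen = np.zeros((n, k), dtype=bool)
    files = dict(zip(manifest["sample_id"].astype(str), manifest["file"]))
    for i, sid in enumerate(kept_ids):
        path = Path(files[sid])
        if base_dir is not None:
            path = Path(base_dir) / path
        records = _parse_coverage_file(path, sid)
        for key, (m, u) in records.items():
            j = by_pos.get(key)
            if j is None:
                report.ignored_records += 1
                continue
            meth_counts[i, j] = m
            totals[i, j] = m + u
            seen[i, j] = True
    keep_sites, site_report = filter_sites(totals, [s.label for s in panel], min_mean_coverage)
    report.excluded_sites.extend(site_report.excluded_sites)
    report.warnings.extend(site_report.warnings)
    values = np.full((n, int(keep_sites.sum())), np.nan)
    kept_sites = [s for s, ok in zip(panel, keep_sites) if ok]
    cols = np.flatnonzero(keep_sites)
    for out_j, j in enumerate(cols):
        for i in range(n):
            if seen[i, j] and totals[i, j] > 0:
                values[i, out_j] = methylation_percent(
                    int(meth_counts[i, j]), int(totals[i, j] - meth_counts[i, j])
                )
    matrix = MethylationMatrix(
        sample_ids=kept_ids, sites=kept_sites, values=values,
        coverage=totals[:, cols],
    )
    return matrix, report
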