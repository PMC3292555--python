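"""Readers and writers for the plain-text formats the pipeline touches.

Formats: BED3/BED4 (chromatin states in column 4, query regions), UCSC
chrom.sizes and cytoBand tables, tab-separated point lists (which must
declare their coordinate base in a ``#base=0`` / ``#base=1`` header line —
no silent guessing), tab-separated genetic maps, and the results TSV.

All readers validate coordinates against the genome layout and reject
out-of-bounds records rather than clamping.  Internally everything is
0-based half-open; 1-based point inputs are converted on read.
"""

from __future__ import annotations

import math
from typing import Iterable, Sequence

import pandas as pd

from .errors import ParseError, ValidationError
from .genome import GenomeLayout, GenomicInterval, PointTrack, SegmentTrack
from .enrichment import OverlapTestResult
from .points import PointOverlapResult
from .regions import GeneticMap

RESULT_COLUMNS = [
    "track_label",
    "bin_id",
    "observed_overlap",
    "enrichment",
    "p_value",
    "fdr_significant",
    "n_null_samples",
]

_SKIP_PREFIXES = ("#", "browser", "track")


def _data_lines(path) -> Iterable[tuple[int, str]]:
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(_SKIP_PREFIXES):
                continue
            yield lineno, line


# ---------------------------------------------------------------------------
# BED
# ---------------------------------------------------------------------------


def _parse_bed_rows(path):
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected >= 3 tab-separated columns")
        chrom = fields[0]
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
        label = fields[3] if len(fields) >= 4 else ""
        rows.append((lineno, chrom, start, end, label))
    return rows


def read_bed(path, layout: GenomeLayout, label: str | None = None) -> SegmentTrack:
    """All intervals of a BED file as one merged track.

    The track label is ``label`` if given, else the file's single distinct
    column-4 value (empty when the file is BED3 or mixes labels).
    """
    rows = _parse_bed_rows(path)
    intervals = [GenomicInterval(c, s, e) for _, c, s, e, _ in rows]
    if label is None:
        labels = {l for *_, l in rows if l}
        label = labels.pop() if len(labels) == 1 else ""
    return SegmentTrack(layout, intervals, label=label)


def read_segmentation(path, layout: GenomeLayout) -> dict[str, SegmentTrack]:
    """A multi-state BED4 split into one merged track per column-4 label."""
    rows = _parse_bed_rows(path)
    grouped: dict[str, list[GenomicInterval]] = {}
    for lineno, chrom, start, end, label in rows:
        if not label:
            raise ParseError(f"{path}:{lineno}: segmentation requires a state label")
        grouped.setdefault(label, []).append(GenomicInterval(chrom, start, end))
    return {
        l: SegmentTrack(layout, ivs, label=l) for l, ivs in sorted(grouped.items())
    }


def write_bed(track: SegmentTrack, path) -> None:
    """Sorted, tab-separated, 0-based half-open; label in column 4 if set."""
    with open(path, "w") as fh:
        for iv in track.intervals:
            cols = [iv.chrom, str(iv.start), str(iv.end)]
            if track.label:
                cols.append(track.label)
            fh.write("\t".join(cols) + "\n")


def write_segmentation(tracks: dict[str, SegmentTrack], path) -> None:
    rows = []
    for label in sorted(tracks):
        rows.extend((iv.chrom, iv.start, iv.end, label) for iv in tracks[label].intervals)
    rows.sort()
    with open(path, "w") as fh:
        for chrom, s, e, label in rows:
            fh.write(f"{chrom}\t{s}\t{e}\t{label}\n")


# ---------------------------------------------------------------------------
# Layout / cytobands
# ---------------------------------------------------------------------------


def read_chrom_sizes(path) -> GenomeLayout:
    chroms = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 2:
            raise ParseError(f"{path}:{lineno}: expected 'name<TAB>length'")
        try:
            chroms.append((fields[0], int(fields[1])))
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer length") from exc
    return GenomeLayout(chromosomes=tuple(chroms))


def write_chrom_sizes(layout: GenomeLayout, path) -> None:
    with open(path, "w") as fh:
        for chrom, length in layout.chromosomes:
            fh.write(f"{chrom}\t{length}\n")


def read_cytoband(path) -> pd.DataFrame:
    """UCSC cytoBand columns: chrom, start, end, band, stain."""
    rows = []
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 4:
            raise ParseError(
                f"{path}:{lineno}: expected chrom, start, end, band[, stain]"
            )
        try:
            rows.append(
                (
                    fields[0],
                    int(fields[1]),
                    int(fields[2]),
                    fields[3],
                    fields[4] if len(fields) > 4 else "",
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer coordinates") from exc
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "band", "stain"])


def write_cytoband(table: pd.DataFrame, path) -> None:
    table.to_csv(path, sep="\t", header=False, index=False)


# ---------------------------------------------------------------------------
# Points
# ---------------------------------------------------------------------------


def read_points(path, layout: GenomeLayout) -> PointTrack:
    """Tab-separated ``id  chrom  pos`` with a mandatory ``#base=0|1`` header."""
    base: int | None = None
    with open(path) as fh:
        lines = fh.read().splitlines()
    records = []
    for lineno, line in enumerate(lines, start=1):
        if line.startswith("#"):
            stripped = line.lstrip("#").strip()
            if stripped in ("base=0", "base=1"):
                base = int(stripped[-1])
            continue
        if not line.strip() or line.startswith(("browser", "track")):
            continue
        if base is None:
            raise ParseError(
                f"{path}:{lineno}: points file must declare '#base=0' or "
                "'#base=1' before any data line"
            )
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'id<TAB>chrom<TAB>pos'")
        try:
            pos = int(fields[2])
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-integer position") from exc
        records.append((fields[0], fields[1], pos - base))
    return PointTrack(layout, records)


def write_points(points: PointTrack, path, base: int = 0) -> None:
    with open(path, "w") as fh:
        fh.write(f"#base={base}\n")
        for pid, chrom, pos in points.records:
            fh.write(f"{pid}\t{chrom}\t{pos + base}\n")


# ---------------------------------------------------------------------------
# Genetic map
# ---------------------------------------------------------------------------


def read_genetic_map(path) -> GeneticMap:
    """Tab-separated ``chrom  pos  cM``; strictly increasing pos per chromosome."""
    per_chrom: dict[str, list[tuple[int, float]]] = {}
    for lineno, line in _data_lines(path):
        fields = line.split("\t")
        if len(fields) < 3:
            raise ParseError(f"{path}:{lineno}: expected 'chrom<TAB>pos<TAB>cM'")
        if fields[1].lower() in ("pos", "position"):  # tolerated column header
            continue
        try:
            per_chrom.setdefault(fields[0], []).append(
                (int(fields[1]), float(fields[2]))
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: non-numeric map entry") from exc
    try:
        return GeneticMap.from_dict(per_chrom)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tcM\n")
        for chrom in gmap.chromosomes:
            pos, cm = gmap.chrom_arrays(chrom)
            for p, c in zip(pos, cm):
                fh.write(f"{chrom}\t{int(p)}\t{c:.6f}\n")


# ---------------------------------------------------------------------------
# Results tables
# ---------------------------------------------------------------------------


def format_p(p: float) -> str:
    """Decimal notation with at least five decimals (e.g. 0.00005)."""
    if not (0 < p <= 1):
        raise ValidationError(f"p-value {p} outside (0, 1]")
    decimals = max(5, int(math.ceil(-math.log10(p))))
    return f"{p:.{decimals}f}"


def results_table(
    results: Sequence[OverlapTestResult | PointOverlapResult],
) -> pd.DataFrame:
    """Uniform results frame: one row per (track, bin)."""
    rows = []
    for r in results:
        if isinstance(r, PointOverlapResult):
            rows.append(
                (r.track_label, "genome", r.n_in_state, r.enrichment, r.p_value,
                 None, r.n_null_samples)
            )
        else:
            rows.append(
                (r.track_label, r.bin_id, r.observed, r.enrichment, r.p_value,
                 r.fdr_significant, r.n_null_samples)
            )
    return pd.DataFrame(rows, columns=RESULT_COLUMNS)


def write_results(table: pd.DataFrame, path) -> None:
    """Deterministic TSV with the fixed header and >= 5-decimal p-values."""
    df = table[RESULT_COLUMNS]
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for _, row in df.iterrows():
            obs = row["observed_overlap"]
            obs_str = str(int(obs)) if float(obs) == int(obs) else f"{obs:.6g}"
            enr = float(row["enrichment"])
            enr_str = "nan" if math.isnan(enr) else f"{enr:.10g}"
            sig = row["fdr_significant"]
            sig_str = "NA" if sig is None or (isinstance(sig, float) and math.isnan(sig)) else str(bool(sig))
            fh.write(
                "\t".join(
                    [
                        str(row["track_label"]),
                        str(row["bin_id"]),
                        obs_str,
                        enr_str,
                        format_p(float(row["p_value"])),
                        sig_str,
                        str(int(row["n_null_samples"])),
                    ]
                )
                + "\n"
            )


def read_results(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(RESULT_COLUMNS) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing result columns {sorted(missing)}")
    df["observed_overlap"] = pd.to_numeric(df["observed_overlap"])
    df["enrichment"] = df["enrichment"].astype(float)
    df["p_value"] = df["p_value"].astype(float)
    df["n_null_samples"] = df["n_null_samples"].astype(int)
    df["fdr_significant"] = df["fdr_significant"].map(
        {"True": True, "False": False, "NA": None}
    )
    return df
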