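"""Seed alignments: the gap-aware multiple alignments that family models derive from.

A seed alignment is the single source of provenance for both the consensus
sequence and the profile HMM of a transposable-element family.  This module
holds the in-memory data model, Stockholm 1.0 I/O, coverage / alignment
quality summaries, and an SVG rendering of the alignment overview (coverage
silhouette plus a per-instance window-quality heatmap, rows sorted by start
position).

Coordinates are 0-based, half-open throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from Bio import AlignIO
from Bio.Align import MultipleSeqAlignment
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import FormatError, ParameterError

GAP_CHARS = {"-", "."}
ALPHABET = set("ACGTN-")


def _normalize_row(row: str) -> str:
    """Map '.' gaps to '-' and validate the alphabet (case-insensitively)."""
    row = row.replace(".", "-")
    bad = set(row.upper()) - ALPHABET
    if bad:
        raise FormatError(f"illegal characters in alignment row: {sorted(bad)}")
    return row


@dataclass
class AlignedInstance:
    """One gapped row of a seed alignment.

    ``source_id`` conventionally encodes provenance as ``genome:start-end:strand``.
    ``start_col``/``end_col`` delimit the covered column span (half-open);
    everything outside it is gap.
    """

    source_id: str
    row: str
    start_col: int = field(init=False)
    end_col: int = field(init=False)

    def __post_init__(self) -> None:
        self.row = _normalize_row(self.row)
        nongap = [i for i, c in enumerate(self.row) if c not in GAP_CHARS]
        if not nongap:
            raise FormatError(f"instance {self.source_id!r} is entirely gaps")
        self.start_col = nongap[0]
        self.end_col = nongap[-1] + 1

    def __len__(self) -> int:
        return len(self.row)

    def ungapped(self) -> str:
        return self.row.replace("-", "")


@dataclass
class SeedAlignment:
    """A family's multiple alignment of representative instances.

    Rows are never reordered by the data model; display order is a rendering
    concern.  ``reference_annotation`` carries an RF-style per-column label
    string when present in the source Stockholm file.
    """

    family_name: str
    instances: list[AlignedInstance]
    reference_annotation: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.instances:
            raise FormatError("seed alignment must contain at least one instance")
        lengths = {len(i) for i in self.instances}
        if len(lengths) != 1:
            raise FormatError(
                f"ragged alignment: row lengths {sorted(lengths)} in family "
                f"{self.family_name!r}"
            )
        if self.reference_annotation is not None:
            self.reference_annotation = self.reference_annotation.replace(".", "-")
            if len(self.reference_annotation) != self.n_cols:
                raise FormatError("reference annotation length != column count")

    @property
    def n_cols(self) -> int:
        return len(self.instances[0])

    @property
    def n_instances(self) -> int:
        return len(self.instances)

    def column(self, c: int) -> str:
        return "".join(inst.row[c] for inst in self.instances)

    def occupancy(self) -> np.ndarray:
        """Fraction of rows with a non-gap character, per column."""
        mat = self.to_matrix()
        return (mat != "-").mean(axis=0)

    def to_matrix(self) -> np.ndarray:
        """Character matrix (n_instances x n_cols), upper-cased."""
        return np.array([list(i.row.upper()) for i in self.instances])


@dataclass
class CoverageProfile:
    """Per-column depth and per-instance window quality for alignment overviews.

    ``per_window_quality[i, w]`` is the fraction identity of instance *i* to
    the consensus over the *w*-th non-overlapping window of consensus
    positions; NaN marks windows with no aligned residue for that instance.
    """

    per_column_depth: np.ndarray
    per_window_quality: np.ndarray
    window: int
    consensus_columns: np.ndarray  # alignment column of each consensus position


# ---------------------------------------------------------------------------
# Stockholm I/O (Bio.AlignIO does the parsing; we validate and diagnose)
# ---------------------------------------------------------------------------

def _diagnose_ragged(path: Path) -> Optional[str]:
    """Best-effort identification of the row whose length disagrees."""
    lengths: dict[str, int] = {}
    order: list[str] = []
    for line in Path(path).read_text().splitlines():
        line = line.rstrip()
        if not line or line.startswith("#") or line == "//":
            continue
        parts = line.split(None, 1)
        if len(parts) != 2:
            continue
        name, seq = parts
        if name not in lengths:
            order.append(name)
        lengths[name] = lengths.get(name, 0) + len(seq)
    if not order:
        return None
    values = list(lengths.values())
    counts = {v: values.count(v) for v in set(values)}
    # majority length; ties resolve to the first row's length
    expected = max(counts, key=lambda v: (counts[v], v == lengths[order[0]]))
    for name in order:
        if lengths[name] != expected:
            return name
    return None


def read_stockholm(path) -> SeedAlignment:
    """Read a Stockholm 1.0 seed alignment (single- or multi-block).

    '.' gaps are normalized to '-'; case is preserved.  Raises
    :class:`FormatError` for empty files and ragged rows (naming the
    offending sequence where it can be identified).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise FormatError(f"{path}: empty Stockholm file")
    try:
        aln = AlignIO.read(str(path), "stockholm")
    except ValueError as exc:
        culprit = _diagnose_ragged(path)
        if culprit is not None:
            raise FormatError(
                f"{path}: ragged alignment, sequence {culprit!r} has a "
                f"different length"
            ) from exc
        raise FormatError(f"{path}: not a valid Stockholm file: {exc}") from exc
    name = path.stem
    gf_id = getattr(aln, "annotations", {}).get("GF", {}) if hasattr(aln, "annotations") else {}
    if isinstance(gf_id, dict) and "ID" in gf_id:
        name = gf_id["ID"][0] if isinstance(gf_id["ID"], list) else gf_id["ID"]
    rf = aln.column_annotations.get("reference_annotation")
    instances = [AlignedInstance(rec.id, str(rec.seq)) for rec in aln]
    return SeedAlignment(family_name=name, instances=instances, reference_annotation=rf)


def write_stockholm(aln: SeedAlignment, path) -> Path:
    """Write a Stockholm 1.0 file ('# STOCKHOLM 1.0' header, '//' terminator).

    Gap characters are emitted as '-'; an ``#=GC RF`` line is written when the
    alignment carries a reference annotation.
    """
    path = Path(path)
    records = [
        SeqRecord(Seq(inst.row), id=inst.source_id, description="")
        for inst in aln.instances
    ]
    msa = MultipleSeqAlignment(records)
    if aln.reference_annotation is not None:
        msa.column_annotations["reference_annotation"] = aln.reference_annotation
    with open(path, "w") as fh:
        AlignIO.write(msa, fh, "stockholm")
    return path


def write_instances_fasta(aln: SeedAlignment, path) -> Path:
    """Export ungapped instance sequences as FASTA."""
    from Bio import SeqIO

    records = [
        SeqRecord(Seq(inst.ungapped()), id=inst.source_id, description="")
        for inst in aln.instances
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    return Path(path)


# ---------------------------------------------------------------------------
# Coverage and window quality
# ---------------------------------------------------------------------------

def coverage_and_quality(
    aln: SeedAlignment,
    consensus: str,
    window: int = 10,
    consensus_columns: Optional[Sequence[int]] = None,
) -> CoverageProfile:
    """Depth per column and fraction-identity per 10-bp window per instance.

    ``consensus`` is the ungapped consensus.  When ``consensus_columns`` is
    omitted the consensus must span every alignment column (one base per
    column); a consensus restricted to a column subset passes its
    ``column_map`` here.  Window quality for an instance counts only the
    positions where the instance has a residue aligned under a consensus
    position; windows with zero such positions are NaN ("absent").
    """
    if window < 1:
        raise ParameterError("window must be >= 1")
    if consensus_columns is None:
        if len(consensus) != aln.n_cols:
            raise ParameterError(
                f"consensus length {len(consensus)} inconsistent with "
                f"{aln.n_cols} alignment columns (pass consensus_columns "
                "for a column-filtered consensus)"
            )
        consensus_columns = np.arange(aln.n_cols)
    else:
        consensus_columns = np.asarray(consensus_columns, dtype=int)
        if len(consensus) != len(consensus_columns):
            raise ParameterError("consensus length != column map length")

    mat = aln.to_matrix()
    depth = (mat != "-").sum(axis=0).astype(int)

    cons = np.array(list(consensus.upper()))
    sub = mat[:, consensus_columns]  # rows restricted to consensus columns
    aligned = sub != "-"
    matches = aligned & (sub == cons[None, :])

    n_pos = len(consensus)
    n_win = math.ceil(n_pos / window)
    quality = np.full((aln.n_instances, n_win), np.nan)
    for w in range(n_win):
        sl = slice(w * window, min((w + 1) * window, n_pos))
        n_aligned = aligned[:, sl].sum(axis=1)
        n_match = matches[:, sl].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            q = np.where(n_aligned > 0, n_match / np.maximum(n_aligned, 1), np.nan)
        quality[:, w] = q
    return CoverageProfile(
        per_column_depth=depth,
        per_window_quality=quality,
        window=window,
        consensus_columns=np.asarray(consensus_columns),
    )


# ---------------------------------------------------------------------------
# SVG rendering
# ---------------------------------------------------------------------------

def _quality_color(q: float) -> str:
    """Linear red (low) -> blue (high) gradient over fraction identity."""
    q = min(max(float(q), 0.0), 1.0)
    r = int(round(220 * (1.0 - q)))
    b = int(round(220 * q))
    return f"rgb({r},40,{b})"


def render_alignment_plot(prof: CoverageProfile, aln: SeedAlignment, path) -> Path:
    """Seed-alignment overview SVG: coverage silhouette over a row heatmap.

    Rows are drawn sorted ascending by ``start_col``; each covered window is
    one cell colored on a red(low)->blue(high) fraction-identity gradient.
    """
    n_rows, n_win = prof.per_window_quality.shape
    if n_rows != aln.n_instances:
        raise ParameterError("profile was not computed from this alignment")
    cell_w, cell_h = 6, 4
    cov_h = 40
    pad = 4
    width = n_win * cell_w + 2 * pad
    height = cov_h + n_rows * cell_h + 3 * pad

    # coverage silhouette over consensus positions, aggregated per window
    depth_at = prof.per_column_depth[prof.consensus_columns]
    max_depth = max(int(depth_at.max()), 1)
    parts = [
        f'<svg xmlns="http://www.w3.org/2000/svg" width="{width}" '
        f'height="{height}" viewBox="0 0 {width} {height}">',
        f'<rect width="{width}" height="{height}" fill="white"/>',
    ]
    pts = [f"{pad},{pad + cov_h}"]
    for w in range(n_win):
        seg = depth_at[w * prof.window : (w + 1) * prof.window]
        d = float(seg.mean()) if len(seg) else 0.0
        y = pad + cov_h - cov_h * d / max_depth
        pts.append(f"{pad + w * cell_w},{y:.2f}")
        pts.append(f"{pad + (w + 1) * cell_w},{y:.2f}")
    pts.append(f"{pad + n_win * cell_w},{pad + cov_h}")
    parts.append(
        f'<polygon points="{" ".join(pts)}" fill="rgb(60,160,60)" '
        'fill-opacity="0.8" stroke="none"/>'
    )

    order = sorted(range(n_rows), key=lambda i: (aln.instances[i].start_col, i))
    y0 = cov_h + 2 * pad
    for out_r, i in enumerate(order):
        for w in range(n_win):
            q = prof.per_window_quality[i, w]
            if np.isnan(q):
                continue
            x = pad + w * cell_w
            y = y0 + out_r * cell_h
            parts.append(
                f'<rect x="{x}" y="{y}" width="{cell_w}" height="{cell_h}" '
                f'fill="{_quality_color(q)}"/>'
            )
    parts.append("</svg>")
    Path(path).write_text("\n".join(parts))
    return Path(path)
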