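"""Reverse-phase protein array level-3 processing.

RPPA slides are probed one antibody at a time, so raw intensities carry
strong antibody- and sample-level location effects. Level-3 processing
removes them in three annotation-driven steps:

1. drop antibodies raised against the host species (mouse) whose signal
   in xenograft material is unspecific (:func:`filter_species`);
2. log2-transform the raw intensities (:func:`log2_transform`);
3. bidirectional median-centering — subtract each antibody row's median,
   then each sample column's median of the row-centered matrix, one pass
   each in that order (:func:`median_center_bidirectional`).

A row-only variant (:func:`median_center_rows`) provides the per-gene
centering used for display-oriented heatmaps of log2 expression.

Missing readings are ignored when medians are computed and propagate
unchanged through every step.
"""

from __future__ import annotations

import logging

import numpy as np

from .io import LINEAR, LOG2, AnalyteMatrix, InvariantError

logger = logging.getLogger("chemoresist")


def filter_species(m: AnalyteMatrix, keep: str = "human") -> AnalyteMatrix:
    """Restrict the matrix to analytes of one species.

    Analytes without a species annotation are kept (and logged); the
    sample set is unchanged. Raises if nothing would remain.
    """
    species = m.species()
    if species is None:
        logger.info("filter_species: no species annotations; matrix returned unchanged")
        return m
    unannotated = species.index[species.isna()].tolist()
    if unannotated:
        logger.info("filter_species: keeping %d unannotated analyte(s): %s",
                    len(unannotated), unannotated[:10])
    mask = species.isna() | (species == keep)
    if not mask.any():
        raise InvariantError(f"species filter keep={keep!r} removes every analyte")
    kept = m.values.loc[mask.to_numpy()]
    dropped = int((~mask).sum())
    if dropped:
        logger.info("filter_species: removed %d analyte(s) with species != %r", dropped, keep)
    return m.with_values(kept)


def log2_transform(m: AnalyteMatrix, offset: float = 0.0) -> AnalyteMatrix:
    """log2(value + offset) on a linear-scale matrix; result is log2 scale."""
    if m.scale != LINEAR:
        raise InvariantError(f"log2_transform expects a linear-scale matrix, got scale={m.scale!r}")
    if offset < 0:
        raise InvariantError(f"offset must be non-negative, got {offset}")
    arr = m.values.to_numpy(dtype=float) + offset
    bad = np.argwhere(arr <= 0)  # NaN comparisons are False, missing cells pass
    if bad.size:
        r, c = bad[0]
        raise InvariantError(
            f"non-positive value at analyte {m.analyte_ids[r]!r}, sample {m.sample_ids[c]!r} "
            f"with offset {offset} (use a positive offset or clean the input)"
        )
    return m.with_values(np.log2(m.values + offset), scale=LOG2)


def _check_no_empty(m: AnalyteMatrix) -> None:
    row_empty = m.values.isna().all(axis=1)
    if row_empty.any():
        raise InvariantError(f"analyte row(s) entirely missing: {list(m.values.index[row_empty])}")
    col_empty = m.values.isna().all(axis=0)
    if col_empty.any():
        raise InvariantError(f"sample column(s) entirely missing: {list(m.values.columns[col_empty])}")


def median_center_bidirectional(m: AnalyteMatrix) -> AnalyteMatrix:
    """One antibody-row median pass, then one sample-column median pass.

    Exactly one pass each, rows first: every output column median is 0
    exactly; row medians retain only the perturbation introduced by the
    column pass. Missing cells are ignored in medians and propagated.
    """
    if m.scale != LOG2:
        raise InvariantError("median centering operates on log2-scale data")
    _check_no_empty(m)
    centered = m.values.sub(m.values.median(axis=1, skipna=True), axis=0)
    centered = centered.sub(centered.median(axis=0, skipna=True), axis=1)
    return m.with_values(centered)


def median_center_rows(m: AnalyteMatrix) -> AnalyteMatrix:
    """Subtract each analyte row's median (gene-wise centering for heatmaps)."""
    if m.scale != LOG2:
        raise InvariantError("median centering operates on log2-scale data")
    row_empty = m.values.isna().all(axis=1)
    if row_empty.any():
        raise InvariantError(f"analyte row(s) entirely missing: {list(m.values.index[row_empty])}")
    return m.with_values(m.values.sub(m.values.median(axis=1, skipna=True), axis=0))
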