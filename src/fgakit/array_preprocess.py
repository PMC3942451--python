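"""Array scan-data preprocessing.

The scanner/gridding software's tabular export (probe × sample signal
intensities, with per-probe replicate-spot CV and local-background SNR) is
cleaned and normalized before any community statistics:

1. **QC filtering** — a probe/sample measurement is discarded when its
   replicate-spot coefficient of variation exceeds 0.8, its signal-to-noise
   ratio falls below 2, or its raw intensity falls below 1000.
2. **CORS normalization** — each sample is rescaled so the total signal of
   the common oligonucleotide reference standard (identical spike-in
   probes) is equal across samples.
3. **Detection calls** — a probe counts as detected in a sample group when
   it survives QC (non-zero) in at least a minimum number of that group's
   samples (default 3).
4. **Family aggregation** — surviving normalized intensities are summed
   per gene family to give the family × sample profile used downstream.

Discarded measurements are masked and treated as true zeros by downstream
abundance computations.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd


@dataclass
class QCThresholds:
    cv_max: float = 0.8
    snr_min: float = 2.0
    intensity_min: float = 1000.0

    def __post_init__(self) -> None:
        if self.cv_max <= 0 or self.snr_min < 1 or self.intensity_min < 0:
            raise ValueError("invalid QC thresholds")


@dataclass
class ScanTable:
    """Probe × sample intensities plus QC companions and annotations.

    ``mask`` is True where a measurement is present (survived QC);
    intensities at masked-out cells are kept at 0.  ``roles`` maps probe ->
    one of experimental/cors/positive/negative; ``groups`` maps sample ->
    group label.
    """

    intensity: pd.DataFrame  # probes × samples
    roles: pd.Series  # probe -> role
    groups: pd.Series  # sample -> group
    cv: pd.DataFrame | None = None
    snr: pd.DataFrame | None = None
    mask: pd.DataFrame = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = pd.DataFrame(
                True, index=self.intensity.index, columns=self.intensity.columns
            )
        if (self.intensity.values < 0).any():
            raise ValueError("negative intensities")
        missing = set(self.intensity.index) - set(self.roles.index)
        if missing:
            raise ValueError(f"probes without a role: {sorted(missing)[:5]} ...")
        missing_s = set(self.intensity.columns) - set(self.groups.index)
        if missing_s:
            raise ValueError(f"samples without a group: {sorted(missing_s)}")

    @property
    def samples(self) -> list[str]:
        return list(self.intensity.columns)

    def experimental_probes(self) -> pd.Index:
        return self.roles.index[self.roles == "experimental"].intersection(
            self.intensity.index
        )

    def cors_probes(self) -> pd.Index:
        return self.roles.index[self.roles == "cors"].intersection(self.intensity.index)


def replicate_cv(replicates: np.ndarray) -> float:
    """CV across replicate spots: sd/mean (population sd, zero-safe)."""
    m = replicates.mean()
    return float(replicates.std() / m) if m > 0 else 0.0


def replicate_snr(signal: np.ndarray, background: np.ndarray) -> float:
    """(mean signal − mean local background) / sd(local background)."""
    sd = background.std()
    if sd == 0:
        return np.inf
    return float((signal.mean() - background.mean()) / sd)


def qc_filter(t: ScanTable, q: QCThresholds | None = None) -> tuple[ScanTable, dict[str, int]]:
    """Mask out failing measurements; returns (filtered copy, removal counts).

    CV > cv_max, SNR < snr_min, or intensity < intensity_min each remove a
    measurement (a cell can be counted under several filters).  Control
    probes are exempt from the intensity filter.  A missing CV or SNR table
    skips that filter with a warning.
    """
    q = q or QCThresholds()
    mask = t.mask.copy()
    counts = {"cv": 0, "snr": 0, "intensity": 0}

    if t.cv is not None:
        bad = (t.cv > q.cv_max) & mask
        counts["cv"] = int(bad.values.sum())
        mask &= ~bad
    else:
        warnings.warn("no CV table supplied; CV filter skipped")
    if t.snr is not None:
        bad = (t.snr < q.snr_min) & mask
        counts["snr"] = int(bad.values.sum())
        mask &= ~bad
    else:
        warnings.warn("no SNR table supplied; SNR filter skipped")

    exempt = t.roles[t.roles != "experimental"].index
    bad = (t.intensity < q.intensity_min) & mask
    bad.loc[bad.index.intersection(exempt)] = False
    counts["intensity"] = int(bad.values.sum())
    mask &= ~bad

    intensity = t.intensity.where(mask, 0.0)
    return replace(t, intensity=intensity, mask=mask), counts


def cors_normalize(t: ScanTable) -> tuple[ScanTable, pd.Series]:
    """Rescale each sample so all CORS totals equal their cross-sample mean.

    Returns (normalized table, per-sample scale factors).  A sample whose
    surviving CORS total is zero is an error (it cannot be normalized).
    """
    cors = t.cors_probes()
    if len(cors) == 0:
        raise ValueError("no CORS probes in table; cannot normalize")
    totals = t.intensity.loc[cors].where(t.mask.loc[cors], 0.0).sum(axis=0)
    zero = totals[totals <= 0]
    if len(zero) > 0:
        raise ValueError(f"zero CORS total in sample(s): {list(zero.index)}")
    reference = totals.mean()
    factors = reference / totals
    intensity = t.intensity.mul(factors, axis=1).where(t.mask, 0.0)
    return replace(t, intensity=intensity), factors


def detection_call(
    t: ScanTable, min_samples: int = 3, scope: str = "per_group"
) -> pd.DataFrame:
    """Probe × group detection table.

    A probe is detected in a group when it is present (unmasked, > 0) in at
    least ``min_samples`` of the group's samples; ``scope='global'``
    collapses all samples into one group.  An extra ``detected`` column
    marks detection in at least one group.
    """
    if min_samples < 1:
        raise ValueError("min_samples must be >= 1")
    present = t.mask & (t.intensity > 0)
    if scope == "global":
        group_of = pd.Series("all", index=t.groups.index)
    elif scope == "per_group":
        group_of = t.groups
    else:
        raise ValueError(f"unknown scope {scope!r}")
    out = {}
    for g in sorted(group_of.unique()):
        cols = [s for s in t.samples if group_of[s] == g]
        if len(cols) < min_samples:
            warnings.warn(
                f"group {g!r} has {len(cols)} samples < min_samples={min_samples}; "
                "it can never detect a probe"
            )
        out[g] = present[cols].sum(axis=1) >= min_samples
    table = pd.DataFrame(out)
    table["detected"] = table.any(axis=1)
    return table


def detected_per_sample(t: ScanTable) -> pd.Series:
    """Number of surviving (present) experimental probes in each sample."""
    exp = t.experimental_probes()
    present = t.mask.loc[exp] & (t.intensity.loc[exp] > 0)
    return present.sum(axis=0)


@dataclass
class GeneFamilyProfile:
    """Family × sample abundance matrix with provenance ('array' or 'ngs')."""

    values: pd.DataFrame
    provenance: str = "array"

    def __post_init__(self) -> None:
        if (self.values.values < 0).any():
            raise ValueError("negative abundances")
        if self.provenance == "ngs":
            sums = self.values.sum(axis=0)
            if (sums > 1 + 1e-9).any():
                raise ValueError("NGS relative abundances must sum to <= 1 per sample")


def aggregate_families(
    t: ScanTable, probe_map: Mapping[str, str]
) -> GeneFamilyProfile:
    """Sum surviving normalized intensities per gene family.

    Control probes are excluded; an experimental probe missing from
    ``probe_map`` is a hard error.  Conserves total signal: the family
    totals sum to the surviving experimental intensity total.
    """
    exp = t.experimental_probes()
    unmapped = [p for p in exp if p not in probe_map]
    if unmapped:
        raise ValueError(f"unmapped experimental probes: {unmapped[:10]}")
    signal = t.intensity.loc[exp].where(t.mask.loc[exp], 0.0)
    fam = pd.Series({p: probe_map[p] for p in exp}, name="family")
    values = signal.groupby(fam).sum()
    return GeneFamilyProfile(values=values, provenance="array")


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_signal_tables(
    signals: str | Path,
    groups: str | Path,
    roles: Mapping[str, str] | None = None,
    cv: str | Path | None = None,
    snr: str | Path | None = None,
) -> ScanTable:
    """Read a probe × sample signal TSV plus a (sample, group) sidecar.

    Probe roles default to 'experimental' except ids starting with
    ``CORS``/``POS``/``NEG`` unless an explicit mapping is given.
    """
    intensity = pd.read_csv(signals, sep="\t", index_col=0)
    gdf = pd.read_csv(groups, sep="\t", index_col=0)
    group_series = gdf.iloc[:, 0].astype(str)
    group_series.index = gdf.index.astype(str)
    if roles is None:
        def infer(pid: str) -> str:
            for prefix, role in (("CORS", "cors"), ("POS", "positive"), ("NEG", "negative")):
                if pid.startswith(prefix):
                    return role
            return "experimental"

        roles_series = pd.Series({p: infer(str(p)) for p in intensity.index})
    else:
        roles_series = pd.Series(dict(roles))
    cv_df = pd.read_csv(cv, sep="\t", index_col=0) if cv else None
    snr_df = pd.read_csv(snr, sep="\t", index_col=0) if snr else None
    return ScanTable(
        intensity=intensity, roles=roles_series, groups=group_series,
        cv=cv_df, snr=snr_df,
    )


def read_geo_series_matrix(
    path: str | Path, groups: Mapping[str, str] | pd.Series | None = None
) -> ScanTable:
    """Parse a GEO series-matrix text file into a :class:`ScanTable`.

    Only the expression table between ``!series_matrix_table_begin`` and
    ``!series_matrix_table_end`` and the ``!Sample_title``/geo-accession
    headers are used.  Group labels come from the ``groups`` mapping
    (sample id -> group); when absent every sample lands in one group.
    """
    header_ids: list[str] | None = None
    rows: list[tuple[str, list[float]]] = []
    in_table = False
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("!series_matrix_table_begin"):
                in_table = True
                continue
            if line.startswith("!series_matrix_table_end"):
                in_table = False
                continue
            if not in_table:
                continue
            fields = [f.strip('"') for f in line.split("\t")]
            if header_ids is None:
                if fields[0] != "ID_REF":
                    raise ValueError(f"expected ID_REF header, got {fields[0]!r}")
                header_ids = fields[1:]
            else:
                rows.append((fields[0], [float(x) if x else np.nan for x in fields[1:]]))
    if header_ids is None:
        raise ValueError(f"{path}: no series-matrix table delimiters found")
    intensity = pd.DataFrame(
        {sid: [r[1][j] for r in rows] for j, sid in enumerate(header_ids)},
        index=[r[0] for r in rows],
    ).fillna(0.0)
    if groups is not None:
        gs = pd.Series(dict(groups)) if not isinstance(groups, pd.Series) else groups
        missing = set(header_ids) - set(gs.index)
        if missing:
            raise ValueError(f"samples without group labels: {sorted(missing)}")
        gs = gs.loc[header_ids]
    else:
        gs = pd.Series("all", index=header_ids)
    roles = pd.Series(
        {p: ("cors" if str(p).startswith("CORS") else "experimental") for p in intensity.index}
    )
    return ScanTable(intensity=intensity, roles=roles, groups=gs)
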