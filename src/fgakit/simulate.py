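"""Synthetic data with known ground truth for every pipeline stage.

Two generators, each with its own RNG stream so a probe set designed on one
set of sequences can be reused across many experiment replicates:

* :func:`simulate_sequences` — gene families as point-mutated copies of a
  random ancestor at a controlled expected pairwise identity, plus
  GC-matched ancestor-free background (decoy) sequences;
* :func:`simulate_experiment` — a hybridization scan table over a designed
  probe set: per-sample family abundances with optional group fold
  changes, probe affinities decreasing in duplex-stability rank,
  multiplicative lognormal noise, additive normal background, CORS
  spike-ins, and random dropouts.

The signal model is the minimal one consistent with scanner data —
``intensity = abundance × affinity × LogNormal(1, cv) + Normal(bg, sd)``
floored at zero — and every drawn quantity is recorded in the returned
truth dictionary.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .array_preprocess import ScanTable
from .probe_design import ProbeSet
from .seqio_db import SequenceRecord, write_fasta
from .specificity import default_nn_params

_BASES = np.array(list("ACGT"))


@dataclass
class SimConfig:
    seed: int = 0
    # sequence generation
    n_families: int = 8
    members_per_family: int = 5
    member_identity: float = 90.0  # expected pairwise percent identity
    cds_length: int = 900
    n_background: int = 100
    # experiment generation
    groups: tuple[str, ...] = ("control", "treatment")
    n_samples_per_group: int = 12
    family_fold_changes: dict[str, float] = field(default_factory=dict)
    family_abundance: dict[str, float] = field(default_factory=dict)
    base_abundance: float = 20000.0
    abundance_sigma: float = 0.5  # lognormal spread of per-family base levels
    noise_cv: float = 0.2
    background_level: float = 200.0
    background_sd: float = 50.0
    cors_level: float = 5000.0
    n_cors: int = 24
    dropout_rate: float = 0.02

    def __post_init__(self) -> None:
        if not 50.0 < self.member_identity <= 100.0:
            raise ValueError("member_identity must be in (50, 100]")
        for rate in (self.noise_cv, self.dropout_rate):
            if not 0.0 <= rate <= 1.0:
                raise ValueError("rates must be in [0, 1]")
        if self.cds_length < 50:
            raise ValueError("cds_length must be at least one probe length")


def _mutation_rate(identity_pct: float) -> float:
    """Per-member ancestor mutation rate giving the requested *pairwise*
    identity in expectation.

    Two members agree at a site with probability (1−m)² + m²/3 (a mutation
    always changes the base, picking uniformly among the three others).
    """
    p = identity_pct / 100.0
    return 0.75 * (1.0 - math.sqrt(max(0.0, 1.0 - (4.0 / 3.0) * (1.0 - p))))


@dataclass
class SimulatedSequences:
    targets: list[tuple[str, SequenceRecord]]
    background: list[SequenceRecord]
    truth: dict

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta([rec for _, rec in self.targets], outdir / "targets.fasta")
        write_fasta(self.background, outdir / "background.fasta")
        with open(outdir / "families.tsv", "w") as fh:
            fh.write("family\tcategory\tmember_id\n")
            for fam, rec in self.targets:
                fh.write(f"{fam}\tsimulated\t{rec.id}\n")
        with open(outdir / "truth.json", "w") as fh:
            json.dump(self.truth, fh, indent=1)


def simulate_sequences(c: SimConfig) -> SimulatedSequences:
    """Generate family members and decoy background with recorded mutations."""
    rng = np.random.default_rng([c.seed, 0])
    m = _mutation_rate(c.member_identity)
    targets: list[tuple[str, SequenceRecord]] = []
    truth: dict = {
        "seed": c.seed,
        "mutation_rate": m,
        "families": {},
    }
    gc_total = 0.0
    for f in range(c.n_families):
        fam = f"fam{f:03d}"
        ancestor = rng.choice(_BASES, size=c.cds_length)
        fam_truth = {"ancestor": "".join(ancestor), "members": {}}
        for j in range(c.members_per_family):
            seq = ancestor.copy()
            sites = np.nonzero(rng.random(c.cds_length) < m)[0]
            for i in sites:
                alternatives = [b for b in "ACGT" if b != seq[i]]
                seq[i] = alternatives[rng.integers(3)]
            sid = f"{fam}_m{j:02d}"
            s = "".join(seq)
            gc_total += sum(1 for b in s if b in "GC") / len(s)
            targets.append((fam, SequenceRecord(id=sid, seq=s, source="target")))
            fam_truth["members"][sid] = {"n_mutations": int(sites.size),
                                         "sites": sites.tolist()}
        truth["families"][fam] = fam_truth
    gc_mean = gc_total / max(1, len(targets))
    background = []
    probs = np.array([(1 - gc_mean) / 2, gc_mean / 2, gc_mean / 2, (1 - gc_mean) / 2])
    for b in range(c.n_background):
        seq = "".join(rng.choice(_BASES, size=c.cds_length, p=probs))
        background.append(SequenceRecord(id=f"bg{b:04d}", seq=seq, source="background"))
    truth["background_gc"] = gc_mean
    return SimulatedSequences(targets=targets, background=background, truth=truth)


def simulate_experiment(
    probes: ProbeSet, c: SimConfig, experiment_seed: int | None = None
) -> tuple[ScanTable, dict]:
    """Generate a scan table over a designed probe set.

    Fold changes in ``c.family_fold_changes`` multiply the listed family's
    abundance in every non-control group (the first group is the control).
    Probe affinity decreases with the rank of the probe's perfect-duplex
    ΔG°37 (most stable probe → affinity 1, weakest → 0.5).
    """
    seed = c.seed if experiment_seed is None else experiment_seed
    rng = np.random.default_rng([seed, 1])
    params = default_nn_params()

    reports = probes.probes
    probe_ids = [r.candidate.probe_id for r in reports]
    fam_of = {r.candidate.probe_id: r.candidate.family for r in reports}
    families = sorted({r.candidate.family for r in reports})

    # per-family base abundances (overridable), fold changes on non-control groups
    base = {}
    for fam in families:
        if fam in c.family_abundance:
            base[fam] = float(c.family_abundance[fam])
        else:
            base[fam] = float(
                rng.lognormal(math.log(c.base_abundance), c.abundance_sigma)
            )
    samples, sample_group = [], {}
    for g in c.groups:
        for i in range(c.n_samples_per_group):
            sid = f"{g}_{i:02d}"
            samples.append(sid)
            sample_group[sid] = g
    abundance = pd.DataFrame(index=families, columns=samples, dtype=float)
    control = c.groups[0]
    for sid in samples:
        g = sample_group[sid]
        for fam in families:
            a = base[fam]
            if g != control:
                a *= c.family_fold_changes.get(fam, 1.0)
            abundance.loc[fam, sid] = a

    # affinities from perfect-duplex stability rank
    dgs = np.array(
        [sum(params.stack_dg[r.candidate.seq[i : i + 2]]
             for i in range(len(r.candidate.seq) - 1))
         for r in reports]
    )
    order = np.argsort(dgs)  # most negative (most stable) first
    affinity = np.empty(len(reports))
    denom = max(1, len(reports) - 1)
    for rank, idx in enumerate(order):
        affinity[idx] = 1.0 - 0.5 * rank / denom

    sigma = math.sqrt(math.log(1.0 + c.noise_cv**2)) if c.noise_cv > 0 else 0.0
    n_p, n_s = len(probe_ids), len(samples)
    ab = np.array([[abundance.loc[fam_of[p], s] for s in samples] for p in probe_ids])
    noise = (
        rng.lognormal(-0.5 * sigma**2, sigma, size=(n_p, n_s)) if sigma > 0
        else np.ones((n_p, n_s))
    )
    bg = rng.normal(c.background_level, c.background_sd, size=(n_p, n_s)) \
        if c.background_sd > 0 else np.full((n_p, n_s), c.background_level)
    signal = np.maximum(ab * affinity[:, None] * noise + bg, 0.0)

    cors_ids = [f"CORS_{i:04d}" for i in range(c.n_cors)]
    cors_signal = np.maximum(
        c.cors_level * rng.lognormal(-0.5 * 0.05**2, 0.05, size=(c.n_cors, n_s)), 0.0
    )

    all_ids = probe_ids + cors_ids
    intensity = pd.DataFrame(
        np.vstack([signal, cors_signal]), index=all_ids, columns=samples
    )
    mask = pd.DataFrame(True, index=all_ids, columns=samples)
    if c.dropout_rate > 0:
        drop = rng.random((n_p, n_s)) < c.dropout_rate
        mask.iloc[:n_p] = ~drop
        intensity.iloc[:n_p] = intensity.iloc[:n_p].where(mask.iloc[:n_p], 0.0)
    cv = pd.DataFrame(
        np.abs(rng.normal(0.3, 0.15, size=(len(all_ids), n_s))),
        index=all_ids, columns=samples,
    )
    snr = (intensity - c.background_level) / max(c.background_sd, 1e-9)
    snr = snr.clip(lower=0.0)
    roles = pd.Series(
        {**{p: "experimental" for p in probe_ids}, **{p: "cors" for p in cors_ids}}
    )
    table = ScanTable(
        intensity=intensity, roles=roles,
        groups=pd.Series(sample_group), cv=cv, snr=snr, mask=mask,
    )
    truth = {
        "seed": seed,
        "config": {k: v for k, v in asdict(c).items()
                   if not isinstance(v, dict) or v},
        "base_abundance": base,
        "fold_changes": dict(c.family_fold_changes),
        "abundance": {f: abundance.loc[f].to_dict() for f in families},
        "affinity": dict(zip(probe_ids, affinity.tolist())),
        "probe_family": fam_of,
        "n_dropouts": int((~mask.values).sum()),
    }
    return table, truth


def probe_family_map(probes: ProbeSet) -> dict[str, str]:
    """probe id -> family mapping for aggregation."""
    return {r.candidate.probe_id: r.candidate.family for r in probes.probes}
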