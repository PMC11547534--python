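"""In-silico altrenogest administration study generator.

Emulates the data a two-route (oral vs intramuscular) equine
administration study produces after LC-HRMS/MS acquisition and alignment:
an aligned feature x sample peak-area table with pooled-QC and external
control injections, injection-order sensitivity drift, and one DDA
product-ion spectrum per feature, plus the ground truth needed to score
every downstream stage.

Study design (defaults)
-----------------------
Urine is collected daily at 8 am over 21 days (0–504 h, 22 time points)
with two frequent-sampling days adding +2/+4/+6/+8/+12 h around the first
and last administrations: day 0 for both routes, day 14 for oral, day 7
for IM — 32 time points per horse.  The default design carries one horse
per route, the oral horse missing its 480 h collection, so after removing
time zero the technical triplicates give (30 + 31) x 3 = 183
post-administration data points.

Abundance model
---------------
Peak areas are log-normal: each (feature, horse, time point) gets one
biological draw shared by its technical triplicates, which then differ by
a smaller technical CV.  Marker features add a post-administration log2
response (both routes) and a between-route log2 effect (applied to IM),
so the IM-vs-oral contrast on post-administration samples equals the
planted effect in expectation.  Pooled QCs are the per-feature mean of
one designated horse's study samples plus technical noise; everything is
finally multiplied by a smooth injection-order drift curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .chem_masses import MolecularFormula, deprotonated_mz, parse_formula
from .fragment_annotation import (
    DIAGNOSTIC_LABELS,
    ProductSpectrum,
    default_diagnostic_ions,
    write_spectra_mgf,
)
from .preprocess import FeatureTable, write_feature_table as _write_table

logger = logging.getLogger(__name__)

__all__ = [
    "StudyDesign",
    "MarkerSpec",
    "DriftModel",
    "SyntheticDataset",
    "default_design",
    "single_horse_design",
    "default_markers",
    "generate_study",
    "write_feature_table",
    "write_mgf",
]

#: LC gradient window (min); feature RTs must fall inside it.
GRADIENT_WINDOW = (0.0, 27.5)

_DAILY = tuple(range(0, 505, 24))  # 22 daily collections, 0-504 h
_FREQ_DAY0 = (2, 4, 6, 8, 12)


def _schedule(group: str) -> Tuple[int, ...]:
    """32-point collection schedule: daily + frequent sampling around the
    first and final administrations (day 14 oral, day 7 IM)."""
    final_day0 = 336 if group == "oral" else 168
    late = tuple(final_day0 + h for h in _FREQ_DAY0)
    return tuple(sorted(_DAILY + _FREQ_DAY0 + late))


@dataclass
class StudyDesign:
    """Who is sampled when, and how injections are sequenced.

    ``horses`` maps horse ID to route ('oral' | 'IM'); ``missing`` maps a
    horse to collection times skipped (e.g. the oral horse's lost 480 h
    sample).  Pooled QCs (aliquots of ``qc_horse``'s samples) are injected
    first and then after every ``qc_every`` study injections; external
    controls close the sequence.
    """

    horses: Dict[str, str]
    replicates: int = 3
    qc_every: int = 10
    n_controls: int = 2
    qc_horse: Optional[str] = None
    missing: Dict[str, Tuple[int, ...]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.horses:
            raise ValueError("design needs at least one horse")
        for h, g in self.horses.items():
            if g not in ("oral", "IM"):
                raise ValueError(f"horse {h!r} has unknown group {g!r}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.qc_every < 1:
            raise ValueError("qc_every must be >= 1")
        if self.n_controls < 0:
            raise ValueError("n_controls must be >= 0")
        if self.qc_horse is None:
            self.qc_horse = sorted(self.horses)[0]
        if self.qc_horse not in self.horses:
            raise ValueError(f"qc_horse {self.qc_horse!r} not in design")

    def time_points(self, horse: str) -> Tuple[int, ...]:
        times = _schedule(self.horses[horse])
        skip = set(self.missing.get(horse, ()))
        times = tuple(t for t in times if t not in skip)
        if times[0] != 0:
            raise ValueError(f"horse {horse!r} lost its 0 h baseline")
        if any(b <= a for a, b in zip(times, times[1:])):
            raise ValueError("time points must be strictly increasing")
        return times

    def study_sample_ids(self) -> List[Tuple[str, str, int, int]]:
        """(sample_id, horse, time_h, replicate) for every study sample,
        ordered horse -> time -> replicate."""
        out = []
        for horse in sorted(self.horses):
            for t in self.time_points(horse):
                for r in range(1, self.replicates + 1):
                    out.append((f"{horse}_t{t:03d}_r{r}", horse, t, r))
        return out

    def build_samples(self) -> pd.DataFrame:
        """Sample metadata table with the injection sequence applied."""
        study = self.study_sample_ids()
        rows = []
        qc_count = 1
        rows.append(("QC_01", "QC", "none", 0.0, 1))
        for k, (sid, horse, t, r) in enumerate(study, start=1):
            rows.append((sid, "sample", self.horses[horse], float(t), r))
            if k % self.qc_every == 0 and k < len(study):
                qc_count += 1
                rows.append((f"QC_{qc_count:02d}", "QC", "none", 0.0, 1))
        for c in range(1, self.n_controls + 1):
            rows.append((f"Control_{c}", "control", "none", 0.0, 1))
        df = pd.DataFrame(
            rows, columns=["sample_id", "role", "group", "time_h", "replicate"]
        ).set_index("sample_id")
        df["injection_order"] = np.arange(1, len(df) + 1)
        return df

    def n_post_administration_points(self) -> int:
        """Replicate-level count of post-administration (t > 0) samples."""
        return sum(
            (len(self.time_points(h)) - 1) * self.replicates for h in self.horses
        )


def default_design() -> StudyDesign:
    """One horse per route, oral missing 480 h: 183 post-admin points."""
    return StudyDesign(
        horses={"oral_1": "oral", "im_1": "IM"},
        missing={"oral_1": (480,)},
        qc_horse="im_1",
    )


def single_horse_design(horse: str, group: str, **kwargs) -> StudyDesign:
    """One-horse batch design, e.g. for per-horse consistency screening."""
    return StudyDesign(horses={horse: group}, **kwargs)


@dataclass
class MarkerSpec:
    """A planted marker compound.

    ``group_log2`` is the IM-minus-oral log2 effect on post-administration
    samples; ``post_log2`` is the administration response shared by both
    routes (post vs 0 h baseline).  ``fragment_template`` gives expected
    MS/MS counts per diagnostic channel for sulfated markers.
    """

    name: str
    formula: MolecularFormula
    rt: float
    base_abundance: float = 1e5
    group_log2: float = 0.0
    post_log2: float = 1.0
    bio_cv: float = 0.6
    tech_cv: float = 0.1
    sulfated: bool = True
    fragment_template: Dict[str, float] = field(default_factory=dict)
    n_decoy_fragments: int = 5

    def __post_init__(self) -> None:
        if isinstance(self.formula, str):
            self.formula = parse_formula(self.formula)
        if self.base_abundance <= 0:
            raise ValueError(f"{self.name}: base abundance must be positive")
        if self.bio_cv < 0 or self.tech_cv < 0:
            raise ValueError(f"{self.name}: CVs must be non-negative")
        lo, hi = GRADIENT_WINDOW
        if not (lo < self.rt < hi):
            raise ValueError(f"{self.name}: RT {self.rt} outside gradient window {GRADIENT_WINDOW}")
        if self.sulfated and not self.fragment_template:
            self.fragment_template = dict(_DEFAULT_SULFATE_TEMPLATE)
        if self.sulfated and not any(v > 0 for v in self.fragment_template.values()):
            raise ValueError(f"{self.name}: sulfated marker needs a nonzero diagnostic channel")

    @property
    def mz(self) -> float:
        return deprotonated_mz(self.formula)


#: expected counts per diagnostic channel of a typical steroid sulfate
_DEFAULT_SULFATE_TEMPLATE: Dict[str, float] = {
    "SO3-.": 2000.0,
    "HSO3-": 600.0,
    "SO4-.": 400.0,
    "HSO4-": 8000.0,
    "NL-SO3": 3000.0,
    "NL-H2SO4": 1200.0,
}


def default_markers() -> List[MarkerSpec]:
    """The five steroid-sulfate markers with their observed between-route
    log2 effects (IM vs oral) and RTs."""
    specs = [
        ("estrone sulfate", "C18H22O5S", 9.333, -3.35, 2.0),
        ("testosterone sulfate", "C19H28O5S", 10.108, -0.936, 1.5),
        ("2-methoxyestradiol sulfate", "C19H26O6S", 8.462, 1.15, 1.0),
        ("pregnenolone sulfate", "C21H32O5S", 12.454, -3.05, 1.0),
        ("cortisol sulfate", "C21H30O8S", 4.963, 0.109, 0.5),
    ]
    return [
        MarkerSpec(name=n, formula=f, rt=rt, group_log2=g, post_log2=p)
        for n, f, rt, g, p in specs
    ]


@dataclass
class DriftModel:
    """Smooth injection-order sensitivity multiplier (linear by default:
    0.8 at the first injection rising to 1.2 at the last)."""

    start: float = 0.8
    end: float = 1.2

    def __post_init__(self) -> None:
        if self.start <= 0 or self.end <= 0:
            raise ValueError("drift multiplier must stay positive")

    def multiplier(self, injection_order: np.ndarray, n_total: int) -> np.ndarray:
        io = np.asarray(injection_order, dtype=float)
        if n_total <= 1:
            return np.full_like(io, self.start)
        return self.start + (self.end - self.start) * (io - 1.0) / (n_total - 1.0)


@dataclass
class SyntheticDataset:
    """Generated table + spectra + ground truth for one study."""

    table: FeatureTable
    spectra: List[ProductSpectrum]
    truth: pd.DataFrame  # per feature: sulfated, marker, group_log2, post_log2
    seed: int


def _cv_to_log2_sigma(cv: float) -> float:
    """sd of log2(area) for a log-normal with the given CV."""
    return math.sqrt(math.log1p(cv * cv)) / math.log(2.0)


def generate_study(
    design: Optional[StudyDesign] = None,
    markers: Optional[Sequence[MarkerSpec]] = None,
    n_background: int = 300,
    drift: Optional[DriftModel] = None,
    seed: int = 0,
    sulfated_background_fraction: float = 0.2,
    background_effect_fraction: float = 0.2,
    missing_rate: float = 0.02,
    avoid_mz: Optional[Sequence[float]] = None,
) -> SyntheticDataset:
    """Generate the full synthetic study; deterministic for a fixed seed.

    ``n_background`` unplanted features accompany the markers; a fraction
    of them are sulfated (diagnostic-bearing spectra) and a fraction carry
    a random post-administration response so the volcano tiers are
    populated.  Background m/z values keep >= 0.06 Da away from every
    theoretical steroid-sulfate list entry (and ``avoid_mz`` extras) so no
    decoy can hit the searcher within ppm tolerance.
    """
    if design is None:
        design = default_design()
    if markers is None:
        markers = default_markers()
    if drift is None:
        drift = DriftModel()
    if n_background < 0:
        raise ValueError("n_background must be non-negative")
    names = [m.name for m in markers]
    if len(set(names)) != len(names):
        raise ValueError("duplicate marker names")

    rng = np.random.default_rng(seed)
    samples = design.build_samples()
    n_total_inj = len(samples)

    from .sulfate_search import default_compounds

    protected = [c.mz for c in default_compounds()]
    if avoid_mz is not None:
        protected += [float(m) for m in avoid_mz]
    protected_arr = np.array(sorted(protected))

    # ---- feature definitions ------------------------------------------
    feat_rows = []  # fid, mz, rt, base, bio_cv, tech_cv, sulfated, marker, g_eff, p_eff
    n_feat = len(markers) + n_background
    width = max(4, len(str(n_feat)))
    for i, m in enumerate(markers):
        fid = f"F{i + 1:0{width}d}"
        obs_mz = m.mz * (1.0 + rng.uniform(-2e-6, 2e-6))  # +/-2 ppm accuracy
        feat_rows.append(
            (fid, obs_mz, m.rt, m.base_abundance, m.bio_cv, m.tech_cv,
             m.sulfated, m.name, m.group_log2, m.post_log2)
        )
    n_sulf_bg = int(round(sulfated_background_fraction * n_background))
    for j in range(n_background):
        fid = f"F{len(markers) + j + 1:0{width}d}"
        while True:
            mz = rng.uniform(150.0, 600.0)
            if np.min(np.abs(protected_arr - mz)) >= 0.06:
                break
        rt = rng.uniform(0.5, 27.0)
        base = 10.0 ** rng.uniform(4.0, 6.0)
        sulfated = j < n_sulf_bg
        p_eff = float(rng.normal(0.0, 2.0)) if rng.random() < background_effect_fraction else 0.0
        feat_rows.append((fid, mz, rt, base, 0.4, 0.1, sulfated, "", 0.0, p_eff))

    fids = [r[0] for r in feat_rows]
    features = pd.DataFrame(
        {"mz": [r[1] for r in feat_rows], "rt": [r[2] for r in feat_rows]},
        index=pd.Index(fids, name="feature_id"),
    )
    truth = pd.DataFrame(
        {
            "sulfated": [r[6] for r in feat_rows],
            "marker": [r[7] for r in feat_rows],
            "group_log2": [r[8] for r in feat_rows],
            "post_log2": [r[9] for r in feat_rows],
        },
        index=features.index,
    )

    # ---- abundances ----------------------------------------------------
    study = design.study_sample_ids()
    areas = pd.DataFrame(
        np.nan, index=features.index, columns=samples.index, dtype=float
    )
    horse_groups = design.horses
    for (fid, _mz, _rt, base, bio_cv, tech_cv, _sulf, _mk, g_eff, p_eff) in feat_rows:
        s_bio = _cv_to_log2_sigma(bio_cv)
        s_tech = _cv_to_log2_sigma(tech_cv)
        b = math.log2(base)
        # one biological draw per horse x time, shared by replicates
        levels: Dict[Tuple[str, int], float] = {}
        for horse in sorted(horse_groups):
            for t in design.time_points(horse):
                mu = b
                if t > 0:
                    mu += p_eff
                    if horse_groups[horse] == "IM":
                        mu += g_eff
                levels[(horse, t)] = mu + rng.normal(0.0, s_bio)
        vals = np.empty(len(study))
        for k, (sid, horse, t, _r) in enumerate(study):
            vals[k] = 2.0 ** (levels[(horse, t)] + rng.normal(0.0, s_tech))
        areas.loc[fid, [s[0] for s in study]] = vals
        # pooled QC: mean of the designated horse's study samples + tech noise
        qh_cols = [s[0] for s in study if s[1] == design.qc_horse]
        pooled = float(np.mean(areas.loc[fid, qh_cols]))
        qc_ids = samples.index[samples["role"] == "QC"]
        areas.loc[fid, qc_ids] = pooled * 2.0 ** rng.normal(0.0, s_tech, size=len(qc_ids))
        # external controls: fresh baseline biology from unrelated horses
        ctrl_ids = samples.index[samples["role"] == "control"]
        if len(ctrl_ids):
            lv = b + rng.normal(0.0, s_bio, size=len(ctrl_ids))
            areas.loc[fid, ctrl_ids] = 2.0 ** (lv + rng.normal(0.0, s_tech, size=len(ctrl_ids)))

    # drift over injection order
    mult = drift.multiplier(samples["injection_order"].to_numpy(), n_total_inj)
    areas = areas * mult[np.newaxis, :]

    # missingness: background features, study samples only (QCs stay complete)
    if missing_rate > 0 and n_background > 0:
        study_cols = samples.index[samples["role"] == "sample"]
        bg_ids = features.index[len(markers):]
        mask = rng.random((len(bg_ids), len(study_cols))) < missing_rate
        block = areas.loc[bg_ids, study_cols].to_numpy()
        # keep at least one observed value per feature
        full_rows = mask.all(axis=1)
        mask[full_rows, 0] = False
        block[mask] = np.nan
        areas.loc[bg_ids, study_cols] = block

    table = FeatureTable(features, samples, areas)

    # ---- spectra -------------------------------------------------------
    diag = {d.label: d for d in default_diagnostic_ions()}
    spectra: List[ProductSpectrum] = []
    templates = {r[0]: markers[i].fragment_template if r[7] else None
                 for i, r in enumerate(feat_rows) if i < len(markers)}
    for i, (fid, mz, rt, *_rest) in enumerate(feat_rows):
        sulfated = feat_rows[i][6]
        # representative sample: study sample with the largest area
        study_cols = samples.index[samples["role"] == "sample"]
        row = areas.loc[fid, study_cols]
        src = str(row.idxmax())
        if sulfated:
            template = templates.get(fid) or dict(_DEFAULT_SULFATE_TEMPLATE)
            if i >= len(markers):  # sulfated background: jitter the template shape
                template = {
                    k: v * rng.uniform(0.5, 1.5) for k, v in _DEFAULT_SULFATE_TEMPLATE.items()
                }
        else:
            template = {}
        peaks_mz, peaks_int = [], []
        for lab, expected in template.items():
            if expected <= 0:
                continue
            ion = diag[lab]
            pmz = ion.mass if ion.kind == "fragment" else mz - ion.mass
            inten = float(rng.poisson(expected))
            if inten > 0 and pmz > 50.0:
                peaks_mz.append(pmz)
                peaks_int.append(inten)
        n_decoy = markers[i].n_decoy_fragments if i < len(markers) else 5
        forbidden = [d.mass for d in diag.values() if d.kind == "fragment"]
        forbidden += [mz - d.mass for d in diag.values() if d.kind == "neutral-loss"]
        forbidden_arr = np.array(forbidden)
        hi = min(400.0, mz - 5.0)
        for _ in range(n_decoy):
            while True:
                dmz = rng.uniform(100.0, hi)
                if np.min(np.abs(forbidden_arr - dmz)) >= 0.05:
                    break
            inten = float(rng.poisson(rng.uniform(300.0, 2500.0)))
            if inten > 0:
                peaks_mz.append(dmz)
                peaks_int.append(inten)
        rt_jitter = rng.normal(0.0, 0.5) / 60.0  # ~0.5 s scan-time offset
        spectra.append(
            ProductSpectrum(
                precursor_mz=mz,
                rt_min=rt + rt_jitter,
                mz=np.array(peaks_mz),
                intensity=np.array(peaks_int),
                polarity="negative",
                sample_id=src,
                title=fid,
            )
        )

    return SyntheticDataset(table=table, spectra=spectra, truth=truth, seed=seed)


def write_feature_table(ds: SyntheticDataset, path, header_lines: Sequence[str] = ()) -> None:
    """Emit the dataset's feature table in the delimited dialect."""
    _write_table(ds.table, path, header_lines=header_lines)


def write_mgf(ds: SyntheticDataset, path) -> None:
    """Emit the dataset's spectra as MGF (one BEGIN/END IONS block each)."""
    write_spectra_mgf(ds.spectra, path)
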