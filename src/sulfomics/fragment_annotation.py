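"""MS/MS spectrum handling and sulfate-diagnostic fragment annotation.

Steroid sulfate conjugates fragment predictably in negative mode: the
sulfate ester yields small sulfur-oxide product ions (SO3-., HSO3-, SO4-.,
HSO4-) and characteristic neutral losses of SO3 and H2SO4 from the
deprotonated molecule.  Each product-ion spectrum is scanned for these six
diagnostic signals, and two summary parameters are computed:

* **IR (intensity ratio)** — summed intensity of all distinct peaks matched
  to any diagnostic, divided by the summed intensity of all peaks.
* **MA (maximum abundance)** — intensity of the largest diagnostic-matched
  peak as a percentage of the base peak.

Together with the six per-channel intensities these drive the downstream
sulfate/non-sulfate clustering.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

from .chem_masses import (
    ELECTRON_MASS,
    IonKind,
    IonSpecies,
    ion_mz,
    monoisotopic_mass,
    parse_formula,
    ppm_delta,
)

logger = logging.getLogger(__name__)

__all__ = [
    "FragmentPeak",
    "ProductSpectrum",
    "DiagnosticIon",
    "DiagnosticMatches",
    "SulfateProfile",
    "default_diagnostic_ions",
    "read_mgf",
    "write_spectra_mgf",
    "match_diagnostics",
    "compute_profile",
    "annotate_spectrum",
    "align_spectra_to_features",
]


@dataclass(frozen=True)
class FragmentPeak:
    mz: float
    intensity: float

    def __post_init__(self) -> None:
        if self.mz <= 0:
            raise ValueError("peak m/z must be positive")
        if self.intensity < 0:
            raise ValueError("peak intensity must be non-negative")


@dataclass
class ProductSpectrum:
    """One DDA product-ion (MS/MS) event.

    RT is stored in minutes internally; MGF RTINSECONDS is converted on
    read.  Peaks are kept sorted by m/z.
    """

    precursor_mz: float
    rt_min: float
    mz: np.ndarray
    intensity: np.ndarray
    polarity: str = "negative"
    sample_id: str = ""
    title: str = ""

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("m/z and intensity arrays differ in length")
        if np.any(self.mz <= 0) or np.any(self.intensity < 0):
            raise ValueError("invalid peak values")
        order = np.argsort(self.mz, kind="stable")
        self.mz = self.mz[order]
        self.intensity = self.intensity[order]

    @property
    def n_peaks(self) -> int:
        return int(self.mz.size)

    @property
    def base_peak_intensity(self) -> float:
        return float(self.intensity.max()) if self.intensity.size else 0.0


@dataclass(frozen=True)
class DiagnosticIon:
    """One diagnostic signal: a product ion m/z or a neutral-loss mass."""

    label: str
    kind: str  # "fragment" | "neutral-loss"
    mass: float

    def __post_init__(self) -> None:
        if self.kind not in ("fragment", "neutral-loss"):
            raise ValueError(f"unknown diagnostic kind {self.kind!r}")
        if self.mass <= 0:
            raise ValueError("diagnostic mass must be positive")


def default_diagnostic_ions() -> Tuple[DiagnosticIon, ...]:
    """The six sulfate diagnostics, with masses computed from constants.

    Fragment ions (electron-inclusive): SO3-. 79.9574, HSO3- 80.9652,
    SO4-. 95.9523, HSO4- 96.9601; neutral losses: SO3 79.9568 Da and
    H2SO4 97.9674 Da.
    """
    def frag(label: str, formula: str, kind: IonKind) -> DiagnosticIon:
        return DiagnosticIon(label, "fragment", ion_mz(IonSpecies(parse_formula(formula), kind)))

    def loss(label: str, formula: str) -> DiagnosticIon:
        return DiagnosticIon(label, "neutral-loss", monoisotopic_mass(parse_formula(formula)))

    return (
        frag("SO3-.", "SO3", IonKind.RADICAL_ANION),
        frag("HSO3-", "HSO3", IonKind.ANION),
        frag("SO4-.", "SO4", IonKind.RADICAL_ANION),
        frag("HSO4-", "HSO4", IonKind.ANION),
        loss("NL-SO3", "SO3"),
        loss("NL-H2SO4", "H2SO4"),
    )


DIAGNOSTIC_LABELS: Tuple[str, ...] = tuple(d.label for d in default_diagnostic_ions())


# ---------------------------------------------------------------------------
# MGF I/O (pyteomics-backed)
# ---------------------------------------------------------------------------

def read_mgf(path) -> List[ProductSpectrum]:
    """Read an MGF file into :class:`ProductSpectrum` objects.

    RTINSECONDS is converted to minutes.  Blocks lacking PEPMASS are
    skipped with a logged warning; a malformed file raises ``ValueError``.
    """
    from pyteomics import mgf as _mgf

    spectra: List[ProductSpectrum] = []
    try:
        with _mgf.MGF(str(path), convert_arrays=1) as reader:
            for block_no, entry in enumerate(reader, start=1):
                params = entry.get("params", {})
                pep = params.get("pepmass")
                if pep is None or pep[0] is None:
                    logger.warning("MGF block %d lacks PEPMASS; skipped", block_no)
                    continue
                rt_s = params.get("rtinseconds")
                rt_min = float(rt_s) / 60.0 if rt_s is not None else float("nan")
                charges = params.get("charge")
                polarity = "negative"
                if charges:
                    polarity = "negative" if int(charges[0]) < 0 else "positive"
                title = str(params.get("title", ""))
                sample_id = str(params.get("sample", ""))
                spectra.append(
                    ProductSpectrum(
                        precursor_mz=float(pep[0]),
                        rt_min=rt_min,
                        mz=entry.get("m/z array", np.empty(0)),
                        intensity=entry.get("intensity array", np.empty(0)),
                        polarity=polarity,
                        sample_id=sample_id,
                        title=title,
                    )
                )
    except ValueError:
        raise
    except Exception as exc:  # pyteomics raises various parser errors
        raise ValueError(f"malformed MGF file {path}: {exc}") from exc
    return spectra


def read_mzml(path) -> List[ProductSpectrum]:
    """Read MS2 scans from an mzML file behind the same spectrum interface."""
    from pyteomics import mzml as _mzml

    spectra: List[ProductSpectrum] = []
    with _mzml.MzML(str(path)) as reader:
        for entry in reader:
            if entry.get("ms level") != 2:
                continue
            precursor = entry["precursorList"]["precursor"][0]
            ion = precursor["selectedIonList"]["selectedIon"][0]
            rt = entry["scanList"]["scan"][0].get("scan start time", float("nan"))
            polarity = "negative" if "negative scan" in entry else "positive"
            spectra.append(
                ProductSpectrum(
                    precursor_mz=float(ion["selected ion m/z"]),
                    rt_min=float(rt),
                    mz=entry["m/z array"],
                    intensity=entry["intensity array"],
                    polarity=polarity,
                    title=str(entry.get("id", "")),
                )
            )
    return spectra


def write_spectra_mgf(spectra: Sequence[ProductSpectrum], path) -> None:
    """Write spectra as standard MGF (PEPMASS, RTINSECONDS, CHARGE 1-)."""
    from pyteomics import mgf as _mgf

    entries = []
    for s in spectra:
        params = {
            "title": s.title,
            "pepmass": (round(float(s.precursor_mz), 5),),
            "rtinseconds": round(float(s.rt_min) * 60.0, 3),
            "charge": [-1 if s.polarity == "negative" else 1],
        }
        if s.sample_id:
            params["sample"] = s.sample_id
        entries.append(
            {"params": params, "m/z array": s.mz, "intensity array": s.intensity}
        )
    with open(path, "w", encoding="utf-8") as fh:
        _mgf.write(entries, fh, key_order=["title", "pepmass", "rtinseconds", "charge", "sample"])


# ---------------------------------------------------------------------------
# diagnostic matching and the SulfateProfile
# ---------------------------------------------------------------------------

@dataclass
class DiagnosticMatches:
    """Per-diagnostic best matched intensity plus the distinct peak set."""

    intensities: Dict[str, float]
    best_peak: Dict[str, Optional[int]]
    matched_peaks: Set[int] = field(default_factory=set)


def match_diagnostics(
    s: ProductSpectrum,
    ions: Sequence[DiagnosticIon] = None,
    tol_da: float = 0.005,
) -> DiagnosticMatches:
    """Match the diagnostic ions/losses in a negative-mode spectrum.

    Fragment entries match peaks with ``|mz - ref| <= tol_da``; neutral
    losses match peaks where the precursor-minus-peak mass difference is
    within ``tol_da`` of the loss mass.  Per diagnostic the most intense
    qualifying peak is recorded; one physical peak may satisfy several
    diagnostics but is counted once in the distinct-peak set.
    """
    if s.polarity != "negative":
        raise ValueError("sulfate diagnostics are defined for negative-mode spectra")
    if ions is None:
        ions = default_diagnostic_ions()
    intensities: Dict[str, float] = {}
    best_peak: Dict[str, Optional[int]] = {}
    matched: Set[int] = set()
    for ion in ions:
        if ion.kind == "fragment":
            delta = np.abs(s.mz - ion.mass)
        else:  # neutral loss: precursor - peak vs loss mass
            delta = np.abs((s.precursor_mz - s.mz) - ion.mass)
        idx = np.nonzero(delta <= tol_da)[0]
        if idx.size:
            best = int(idx[np.argmax(s.intensity[idx])])
            intensities[ion.label] = float(s.intensity[best])
            best_peak[ion.label] = best
            matched.update(int(j) for j in idx)
        else:
            intensities[ion.label] = 0.0
            best_peak[ion.label] = None
    return DiagnosticMatches(intensities, best_peak, matched)


@dataclass(frozen=True)
class SulfateProfile:
    """Six diagnostic-channel intensities plus IR (fraction) and MA (%)."""

    channels: Mapping[str, float]
    ir: float
    ma: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.ir <= 1.0 + 1e-12:
            raise ValueError(f"IR out of [0,1]: {self.ir}")
        if not 0.0 <= self.ma <= 100.0 + 1e-9:
            raise ValueError(f"MA out of [0,100]: {self.ma}")
        if (self.ir == 0) != (self.ma == 0):
            raise ValueError("IR and MA must vanish together")


def compute_profile(s: ProductSpectrum, matches: DiagnosticMatches) -> SulfateProfile:
    """IR and MA from a spectrum and its diagnostic matches."""
    total = float(s.intensity.sum())
    if total <= 0:
        raise ValueError("spectrum has zero total intensity")
    matched_idx = sorted(matches.matched_peaks)
    matched_sum = float(s.intensity[matched_idx].sum()) if matched_idx else 0.0
    ir = matched_sum / total
    if matched_idx:
        ma = 100.0 * float(s.intensity[matched_idx].max()) / s.base_peak_intensity
    else:
        ma = 0.0
    return SulfateProfile(dict(matches.intensities), ir, ma)


def annotate_spectrum(
    s: ProductSpectrum,
    ions: Sequence[DiagnosticIon] = None,
    tol_da: float = 0.005,
) -> SulfateProfile:
    """Convenience: match diagnostics and compute the profile in one step."""
    return compute_profile(s, match_diagnostics(s, ions, tol_da))


# ---------------------------------------------------------------------------
# spectrum -> feature alignment
# ---------------------------------------------------------------------------

def align_spectra_to_features(
    spectra: Sequence[ProductSpectrum],
    features,  # DataFrame indexed by feature ID with mz and rt columns
    rt_tol_s: float = 3.0,
    mz_tol_ppm: float = 5.0,
    frag_tol_da: float = 0.005,
    ions: Sequence[DiagnosticIon] = None,
) -> Dict[str, SulfateProfile]:
    """Attach one :class:`SulfateProfile` per aligned feature.

    Each spectrum is assigned to the feature minimising |ppm deviation|
    among those within both the RT (seconds) and m/z (ppm) tolerances;
    ties break on smaller |RT difference|, then lexicographically smaller
    feature ID.  When several spectra land on one feature, the one with
    the largest base peak (a precursor-intensity proxy) wins.  Unmatched
    spectra are counted in a log message.
    """
    if ions is None:
        ions = default_diagnostic_ions()
    rt_tol_min = rt_tol_s / 60.0
    fmz = features["mz"].to_numpy(dtype=float)
    frt = features["rt"].to_numpy(dtype=float)
    fids = list(features.index)
    chosen: Dict[str, Tuple[float, ProductSpectrum]] = {}
    unmatched = 0
    for s in spectra:
        drt = np.abs(frt - s.rt_min)
        dppm = np.abs((s.precursor_mz - fmz) / fmz) * 1e6
        cand = np.nonzero((drt <= rt_tol_min) & (dppm <= mz_tol_ppm))[0]
        if cand.size == 0:
            unmatched += 1
            continue
        ranked = sorted(cand, key=lambda j: (dppm[j], drt[j], fids[j]))
        fid = fids[ranked[0]]
        bp = s.base_peak_intensity
        if fid not in chosen or bp > chosen[fid][0]:
            chosen[fid] = (bp, s)
    if unmatched:
        logger.info("align_spectra_to_features: %d spectra unassigned", unmatched)
    return {
        fid: annotate_spectrum(s, ions, frag_tol_da)
        for fid, (_, s) in sorted(chosen.items())
    }
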