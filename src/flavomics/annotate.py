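"""Suspect-screening annotation of MS1 features and MS/MS spectra.

Accurate-mass screening against the suspect library, consecutive
neutral-loss chain walking over the candidate's residue multiset, and
diagnostic product-ion confirmation (protonated/native-cation aglycone ion,
acyl-glycan fragment ions with charge retained on the glycan).

Loss chains are walked over "loss units": each sugar residue is a unit and
each acyl residue may be lost either alone or together with one sugar as a
combined acyl-glycan unit (the fragmentation commonly observed for acylated
glycoconjugates).  Every ordering of every unit decomposition is scored by
how many ladder ions are found in the spectrum; the best-supported ordering
is reported.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import PROTON_MASS, ppm_error
from .library import (
    FAMILIES,
    GLYCO_CLASSES,
    CompoundRecord,
    SuspectLibrary,
)
from .peaklists import SpectrumRecord

logger = logging.getLogger(__name__)

__all__ = [
    "MatchedLoss",
    "DiagnosticIon",
    "AnnotationResult",
    "DatasetAnnotation",
    "screen_ms1",
    "annotate_msms",
    "annotate_dataset",
]

TIERS = ("ms1_only", "partial_ms2", "full_chain")


@dataclass(frozen=True)
class MatchedLoss:
    """One matched rung of a neutral-loss ladder."""

    unit: tuple[str, ...]  # residue keys lost in this step
    from_mz: float
    to_mz: float  # theoretical
    observed_mz: float
    expected_loss: float
    observed_loss: float
    mda_error: float


@dataclass(frozen=True)
class DiagnosticIon:
    role: str  # "aglycone_ion" | "acyl_glycan"
    expected_mz: float
    observed_mz: float


@dataclass
class AnnotationResult:
    """A compound assignment for one feature with its supporting evidence."""

    feature_id: str
    compound: CompoundRecord
    ms1_ppm: float
    matched_losses: list[MatchedLoss] = field(default_factory=list)
    matched_diagnostic_ions: list[DiagnosticIon] = field(default_factory=list)
    tier: str = "ms1_only"
    rt_delta: float | None = None

    @property
    def tier_rank(self) -> int:
        return TIERS.index(self.tier)


def screen_ms1(
    features: Sequence[SpectrumRecord],
    lib: SuspectLibrary,
    tol_ppm: float = 10.0,
    rt_window: float | None = None,
) -> list[tuple[SpectrumRecord, CompoundRecord, float]]:
    """Accurate-mass (and optional RT) matching of features to suspects.

    Returns every (feature, compound, ppm) pair whose precursor m/z lies
    within ``tol_ppm`` of the compound's theoretical precursor; when
    ``rt_window`` is given and both RTs are known, the RT difference must
    also be within the window.
    """
    if tol_ppm <= 0:
        raise ValueError("tol_ppm must be positive")
    hits = []
    for feat in features:
        for comp in lib.compounds:
            err = ppm_error(feat.precursor_mz, comp.precursor_mz)
            if abs(err) > tol_ppm:
                continue
            if (
                rt_window is not None
                and feat.retention_time is not None
                and comp.retention_time is not None
                and abs(feat.retention_time - comp.retention_time) > rt_window
            ):
                continue
            hits.append((feat, comp, err))
    return hits


def _loss_unit_decompositions(
    compound: CompoundRecord, lib: SuspectLibrary
) -> list[list[tuple[str, ...]]]:
    """All ways to group the residue multiset into loss units.

    Sugars are always single-residue units; each acyl is lost either alone
    or paired with one distinct sugar (acyl-glycan unit).
    """
    sugars = [k for k in compound.residues if lib.residue(k).klass == "sugar"]
    acyls = [k for k in compound.residues if lib.residue(k).klass == "acyl"]

    decomps: list[list[tuple[str, ...]]] = []
    n = len(sugars)
    for pairing in itertools.product(range(n + 1), repeat=len(acyls)):
        # pairing[i] == n means acyl i is lost alone; < n pairs it with sugar j
        used = [p for p in pairing if p < n]
        if len(used) != len(set(used)):
            continue
        units: list[tuple[str, ...]] = []
        paired = set(used)
        for j, s in enumerate(sugars):
            if j not in paired:
                units.append((s,))
        for i, a in enumerate(acyls):
            if pairing[i] < n:
                units.append((a, sugars[pairing[i]]))
            else:
                units.append((a,))
        decomps.append(units)
    # dedupe (identical sugars make some pairings equivalent)
    seen = set()
    unique = []
    for units in decomps:
        key = tuple(sorted(units))
        if key not in seen:
            seen.add(key)
            unique.append(units)
    return unique


def _best_peak(peaks: Sequence[tuple[float, float]], mz: float, tol_mda: float) -> float | None:
    """Observed m/z of the closest peak within tolerance, else None."""
    best, best_d = None, tol_mda / 1e3
    for pmz, _ in peaks:
        d = abs(pmz - mz)
        if d <= best_d:
            best, best_d = pmz, d
    return best


def annotate_msms(
    spectrum: SpectrumRecord,
    candidate: CompoundRecord,
    lib: SuspectLibrary,
    frag_tol_mda: float = 5.0,
) -> AnnotationResult:
    """Score a candidate against a spectrum by neutral-loss chain walking.

    The ladder starts at the candidate's theoretical precursor m/z and
    subtracts loss-unit masses; the final rung is the aglycone ion
    (protonated aglycone, or the native cation for anthocyanidins).  The
    ordering with the most matched rungs wins; complete ladders are
    preferred over incomplete ones of equal match count, and ties are broken
    toward orderings that lose plain sugars before acyl-bearing units.

    Tier: ``full_chain`` when a fully matched ladder connects precursor to
    aglycone ion (for residue-free compounds: the aglycone ion itself is
    observed); ``partial_ms2`` when any rung or diagnostic ion matched;
    ``ms1_only`` otherwise.
    """
    result = AnnotationResult(
        feature_id=spectrum.feature_id,
        compound=candidate,
        ms1_ppm=ppm_error(spectrum.precursor_mz, candidate.precursor_mz),
    )
    peaks = spectrum.ms2_peaks
    if not peaks:
        return result

    residue_mass = {r.key: r.mass for r in lib.residues}
    aglycone_mz = candidate.aglycone.ion_mz

    # diagnostic ions ------------------------------------------------------
    diagnostics: list[DiagnosticIon] = []
    obs = _best_peak(peaks, aglycone_mz, frag_tol_mda)
    aglycone_seen = obs is not None
    if aglycone_seen:
        diagnostics.append(DiagnosticIon("aglycone_ion", aglycone_mz, obs))

    sugars = [k for k in candidate.residues if lib.residue(k).klass == "sugar"]
    acyls = [k for k in candidate.residues if lib.residue(k).klass == "acyl"]
    seen_mzs: set[float] = set()
    for a in acyls:
        for r in range(1, len(sugars) + 1):
            for combo in set(itertools.combinations(sugars, r)):
                mz = residue_mass[a] + sum(residue_mass[s] for s in combo) + PROTON_MASS
                if mz in seen_mzs:
                    continue
                seen_mzs.add(mz)
                obs = _best_peak(peaks, mz, frag_tol_mda)
                if obs is not None:
                    diagnostics.append(DiagnosticIon("acyl_glycan", mz, obs))
    result.matched_diagnostic_ions = diagnostics

    # loss-chain walking ---------------------------------------------------
    best_losses: list[MatchedLoss] = []
    best_key: tuple | None = None
    best_complete = False
    for units in _loss_unit_decompositions(candidate, lib):
        for ordering in set(itertools.permutations(units)):
            mz = candidate.precursor_mz
            losses: list[MatchedLoss] = []
            all_matched = True
            for unit in ordering:
                loss_mass = sum(residue_mass[k] for k in unit)
                next_mz = mz - loss_mass
                obs = _best_peak(peaks, next_mz, frag_tol_mda)
                if obs is None:
                    all_matched = False
                else:
                    losses.append(
                        MatchedLoss(
                            unit=unit,
                            from_mz=mz,
                            to_mz=next_mz,
                            observed_mz=obs,
                            expected_loss=loss_mass,
                            observed_loss=mz - obs,
                            mda_error=(obs - next_mz) * 1e3,
                        )
                    )
                mz = next_mz
            # prefer: more rungs matched; complete ladder; sugar-first order
            sugar_first = tuple(len(u) == 1 and u[0] in sugars for u in ordering)
            key = (len(losses), all_matched, sugar_first, tuple(ordering))
            if best_key is None or key > best_key:
                best_key = key
                best_losses = losses
                best_complete = all_matched and len(losses) == len(ordering)
    result.matched_losses = best_losses

    if candidate.residues:
        full = best_complete and aglycone_seen
    else:
        full = aglycone_seen
    if full:
        result.tier = "full_chain"
    elif best_losses or diagnostics:
        result.tier = "partial_ms2"
    return result


@dataclass
class DatasetAnnotation:
    """Best-per-feature annotations plus the unannotated remainder."""

    results: list[AnnotationResult]
    unannotated: list[SpectrumRecord]
    runners_up: dict[str, list[AnnotationResult]] = field(default_factory=dict)

    def table(self) -> pd.DataFrame:
        rows = []
        for r in self.results:
            rows.append(
                {
                    "feature_id": r.feature_id,
                    "compound": r.compound.name,
                    "family": r.compound.family,
                    "glyco_class": r.compound.glyco_class,
                    "acylated": r.compound.acylated,
                    "ms1_ppm": round(r.ms1_ppm, 3),
                    "tier": r.tier,
                    "matched_losses": ";".join(
                        "+".join(l.unit) for l in r.matched_losses
                    ),
                }
            )
        return pd.DataFrame(
            rows,
            columns=[
                "feature_id", "compound", "family", "glyco_class",
                "acylated", "ms1_ppm", "tier", "matched_losses",
            ],
        )

    def family_census(self) -> dict[str, int]:
        names = {r.compound.name: r.compound for r in self.results}
        out = {fam: 0 for fam in FAMILIES}
        for comp in names.values():
            out[comp.family] += 1
        return out

    def glyco_census(self) -> dict[str, int]:
        names = {r.compound.name: r.compound for r in self.results}
        out = {g: 0 for g in GLYCO_CLASSES}
        for comp in names.values():
            out[comp.glyco_class] += 1
        return out

    def n_compounds(self) -> int:
        return len({r.compound.name for r in self.results})

    def write_tsv(self, path: str | Path, header_lines: Iterable[str] = ()) -> None:
        with open(path, "w") as fh:
            for line in header_lines:
                fh.write(f"# {line}\n")
            self.table().to_csv(fh, sep="\t", index=False)


def annotate_dataset(
    features: Sequence[SpectrumRecord],
    lib: SuspectLibrary,
    ms1_tol_ppm: float = 10.0,
    frag_tol_mda: float = 5.0,
    rt_window: float | None = None,
) -> DatasetAnnotation:
    """Best annotation per feature (one compound per feature).

    Candidates pass the MS1 gate, are scored by MS/MS, and the winner is
    chosen by (tier, |ms1 ppm|, RT proximity to the library entry, name).
    RT is advisory: it resolves positional isomers of identical composition
    but never rejects a candidate unless ``rt_window`` is set.
    """
    hits = screen_ms1(features, lib, ms1_tol_ppm, rt_window)
    by_feature: dict[str, list[tuple[SpectrumRecord, CompoundRecord, float]]] = {}
    for feat, comp, err in hits:
        by_feature.setdefault(feat.feature_id, []).append((feat, comp, err))

    results: list[AnnotationResult] = []
    runners: dict[str, list[AnnotationResult]] = {}
    unannotated: list[SpectrumRecord] = []
    for feat in features:
        cands = by_feature.get(feat.feature_id, [])
        if not cands:
            unannotated.append(feat)
            continue
        scored = []
        for _, comp, _ in cands:
            res = annotate_msms(feat, comp, lib, frag_tol_mda)
            if feat.retention_time is not None and comp.retention_time is not None:
                res.rt_delta = abs(feat.retention_time - comp.retention_time)
            scored.append(res)
        scored.sort(
            key=lambda r: (
                -r.tier_rank,
                abs(r.ms1_ppm),
                r.rt_delta if r.rt_delta is not None else float("inf"),
                r.compound.name,
            )
        )
        results.append(scored[0])
        if len(scored) > 1:
            runners[feat.feature_id] = scored[1:]
    logger.info(
        "annotated %d/%d features (%d compounds)",
        len(results), len(features), len({r.compound.name for r in results}),
    )
    return DatasetAnnotation(results, unannotated, runners)
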