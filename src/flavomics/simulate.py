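"""Synthetic spectra and intensity matrices with the study's structure.

``generate_spectra`` emulates positive-mode [M+H]+ (or native-cation)
spectra of the library compounds: the precursor plus every glycosidic
neutral-loss intermediate, the aglycone ion and acyl-glycan diagnostic
ions, with configurable ppm jitter and fragment dropout.

``generate_intensities`` draws log-normal intensities over a full factorial
design (cultivars x tissues x treatments x biological replicates x
injections), with per-compound baselines constructed to honour tissue-level
family (or glycosylation-class) composition targets and per-compound
treatment effects expressed as true log2 fold changes.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .chem import PROTON_MASS
from .library import SuspectLibrary, classify_glyco
from .peaklists import SpectrumRecord
from .stats import IntensityMatrix

__all__ = [
    "StudyDesign",
    "SimulationTruth",
    "generate_spectra",
    "generate_intensities",
    "make_truth",
    "paper_like_truth",
    "null_truth",
    "truth_report",
    "write_truth",
    "read_truth",
    "DEFAULT_FAMILY_SHARES",
    "DEFAULT_LEAF_ROOT_RATIOS",
    "TREATMENT_EFFECTS_LOG2FC",
]

CULTIVARS = ("LR1", "LR2", "LR3", "LR4")
TISSUES = ("leaf", "root")
TREATMENTS = ("control", "Hg")


@dataclass(frozen=True)
class StudyDesign:
    """The factorial sampling design of the study."""

    cultivars: tuple[str, ...] = CULTIVARS
    tissues: tuple[str, ...] = TISSUES
    treatments: tuple[str, ...] = TREATMENTS
    biological_replicates: int = 3
    injections: int = 3

    def __post_init__(self) -> None:
        if min(len(self.cultivars), len(self.tissues), len(self.treatments)) < 1:
            raise ValueError("all design factors need >=1 level")
        if self.biological_replicates < 1 or self.injections < 1:
            raise ValueError("replicates and injections must be >=1")

    @property
    def n_samples(self) -> int:
        return (
            len(self.cultivars)
            * len(self.tissues)
            * len(self.treatments)
            * self.biological_replicates
            * self.injections
        )

    def sample_table(self) -> pd.DataFrame:
        rows = []
        for cv, ti, tr, b, i in itertools.product(
            self.cultivars,
            self.tissues,
            self.treatments,
            range(1, self.biological_replicates + 1),
            range(1, self.injections + 1),
        ):
            rows.append(
                {
                    "sample_id": f"{cv}_{ti}_{tr}_b{b}_i{i}",
                    "cultivar": cv,
                    "tissue": ti,
                    "treatment": tr,
                    "replicate": b,
                    "injection": i,
                }
            )
        return pd.DataFrame(rows).set_index("sample_id")


@dataclass
class SimulationTruth:
    """Ground truth for one simulation scenario.

    ``baselines`` and ``effects`` are DataFrames indexed by compound with
    one column per (tissue, cultivar) pair; both are on the log2 scale
    (effects are true log2 fold changes of the Hg arm vs control).
    """

    baselines: pd.DataFrame
    effects: pd.DataFrame
    biological_sd: float = 0.25
    technical_sd: float = 0.15
    name: str = "custom"

    def __post_init__(self) -> None:
        if self.biological_sd < 0 or self.technical_sd < 0:
            raise ValueError("noise SDs must be >= 0")
        if not self.baselines.index.equals(self.effects.index) or list(
            self.baselines.columns
        ) != list(self.effects.columns):
            raise ValueError("baselines and effects must share index/columns")


# ---------------------------------------------------------------------------
# spectra


def generate_spectra(
    lib: SuspectLibrary,
    ppm_jitter: float = 0.0,
    frag_dropout: float = 0.0,
    seed: int | None = None,
) -> list[SpectrumRecord]:
    """One synthetic spectrum per library compound.

    The precursor sits at the theoretical m/z perturbed by
    Normal(0, ppm_jitter) ppm; MS2 contains every loss-chain intermediate
    (sugars lost one by one, then acyls), the aglycone ion and the
    acyl-glycan diagnostic ions, each independently dropped with
    probability ``frag_dropout`` and perturbed by the same ppm jitter.
    """
    if ppm_jitter < 0:
        raise ValueError("ppm_jitter must be >= 0")
    if not 0 <= frag_dropout < 1:
        raise ValueError("frag_dropout must be in [0, 1)")
    rng = np.random.default_rng(seed)
    residue = {r.key: r for r in lib.residues}

    def jitter(mz: float) -> float:
        if ppm_jitter == 0:
            return mz
        return mz * (1.0 + rng.normal(0.0, ppm_jitter) * 1e-6)

    records = []
    for i, comp in enumerate(lib.compounds, start=1):
        # canonical loss order: sugars (sorted) first, then acyls
        sugars = sorted(k for k in comp.residues if residue[k].klass == "sugar")
        acyls = sorted(k for k in comp.residues if residue[k].klass == "acyl")
        fragment_mzs: list[float] = []
        mz = comp.precursor_mz
        for key in sugars + acyls:
            mz -= residue[key].mass
            fragment_mzs.append(mz)
        agly_mz = comp.aglycone.ion_mz
        if not any(abs(agly_mz - f) < 1e-9 for f in fragment_mzs):
            fragment_mzs.append(agly_mz)
        for a in acyls:
            for r in range(1, len(sugars) + 1):
                for combo in sorted(set(itertools.combinations(sugars, r))):
                    ion = residue[a].mass + sum(residue[s].mass for s in combo) + PROTON_MASS
                    if not any(abs(ion - f) < 1e-9 for f in fragment_mzs):
                        fragment_mzs.append(ion)

        peaks = []
        for j, fmz in enumerate(fragment_mzs):
            if frag_dropout > 0 and rng.random() < frag_dropout:
                continue
            peaks.append((jitter(fmz), 1000.0 / (j + 1)))
        records.append(
            SpectrumRecord(
                feature_id=f"F{i:03d}",
                precursor_mz=jitter(comp.precursor_mz),
                retention_time=comp.retention_time,
                ms2_peaks=peaks,
            )
        )
    return records


# ---------------------------------------------------------------------------
# intensity truth construction

#: Tissue-level family composition targets (fractions of total signal).
DEFAULT_FAMILY_SHARES: dict[str, dict[str, float]] = {
    "leaf": {
        "flavone": 0.87,
        "anthocyanidin": 0.05,
        "isoflavone": 0.05,
        "pterocarpan": 0.02,
        "flavanone": 0.01,
    },
    "root": {
        "isoflavone": 0.82,
        "flavone": 0.08,
        "pterocarpan": 0.06,
        "anthocyanidin": 0.02,
        "flavanone": 0.02,
    },
}

#: Leaf/root total-intensity ratios per cultivar (ordered by tolerance).
DEFAULT_LEAF_ROOT_RATIOS: dict[str, float] = {
    "LR1": 4.6,
    "LR2": 7.0,
    "LR3": 7.2,
    "LR4": 16.0,
}

#: True treatment effects (log2 FC, Hg vs control) of the differential
#: preset: compound -> {(tissue, cultivar): log2fc}.
TREATMENT_EFFECTS_LOG2FC: dict[str, dict[tuple[str, str], float]] = {
    "Afrormosin": {("root", "LR2"): 3.3, ("root", "LR4"): 2.3},
    "Afrormosin Glc I": {("root", "LR4"): 3.3},
    "Afrormosin MalGlc": {("leaf", "LR2"): 1.4, ("root", "LR2"): 1.6},
    "Apigenin GlcAGlcA": {("root", "LR1"): 2.4},
    "Apigenin FerGlcAGlcAGlcA I": {("root", "LR2"): 3.7, ("root", "LR3"): 1.6},
    "Apigenin CouGlcAGlcAGlcA I": {("root", "LR2"): 3.6, ("root", "LR3"): 3.8},
    "Apigenin FerGlcAGlcAGlcA II": {("root", "LR4"): 2.1},
    "Biochanin A MalGlc I": {
        ("leaf", "LR2"): 0.5,
        ("root", "LR2"): 2.7,
        ("root", "LR3"): 2.2,
        ("root", "LR4"): 2.2,
    },
    "Biochanin A MalGlc II": {
        ("leaf", "LR1"): 2.1,
        ("root", "LR2"): 1.7,
        ("root", "LR3"): 2.1,
        ("root", "LR4"): 1.8,
    },
    "Biochanin A": {
        ("root", "LR2"): 1.3,
        ("root", "LR3"): 1.4,
        ("root", "LR4"): 1.9,
    },
    "Daidzein": {
        ("leaf", "LR1"): 2.6,
        ("leaf", "LR2"): 1.9,
        ("root", "LR2"): 3.4,
        ("root", "LR3"): 1.6,
        ("root", "LR4"): 2.3,
    },
    "Formononetin": {
        ("leaf", "LR3"): 2.1,
        ("root", "LR3"): 1.6,
        ("root", "LR4"): 1.8,
    },
    "Formononetin Glc II": {
        ("leaf", "LR1"): 1.4,
        ("leaf", "LR2"): 2.4,
        ("root", "LR3"): 2.3,
        ("root", "LR4"): 2.6,
    },
    "Formononetin MalGlc": {
        ("leaf", "LR1"): 1.4,
        ("leaf", "LR2"): 3.3,
        ("root", "LR2"): 2.4,
        ("root", "LR3"): 2.5,
        ("root", "LR4"): 1.8,
    },
    "Irisolidone": {
        ("root", "LR2"): 1.6,
        ("root", "LR3"): 3.7,
        ("root", "LR4"): 2.9,
    },
    "Irisolidone isomer": {
        ("leaf", "LR1"): 1.6,
        ("leaf", "LR3"): 1.6,
        ("root", "LR2"): 1.6,
        ("root", "LR4"): 1.3,
    },
    "Medicarpin MalGlc I": {
        ("root", "LR2"): 2.5,
        ("root", "LR3"): 2.4,
        ("root", "LR4"): 1.9,
    },
    "Medicarpin MalGlc II": {
        ("leaf", "LR1"): 2.6,
        ("leaf", "LR3"): 2.4,
        ("leaf", "LR4"): 4.1,
        ("root", "LR2"): 1.5,
    },
    "Peonidin Glc I": {
        ("leaf", "LR1"): 2.9,
        ("leaf", "LR3"): 1.8,
        ("leaf", "LR4"): 1.6,
    },
    "Tricin GlcAGlcA": {("root", "LR2"): 3.3, ("root", "LR4"): 1.4},
    "Tricin Glc I": {("root", "LR3"): 3.1},
    "Tricin FerGlcAGlcA I": {("root", "LR2"): 3.1},
    "Tricin CouGlcAGlcA I": {("root", "LR1"): 3.1, ("root", "LR2"): 4.8},
    "Tricin FerGlcAGlcA III": {("leaf", "LR1"): 2.2},
}


def _group_columns(design: StudyDesign) -> list[tuple[str, str]]:
    return [(t, c) for t in design.tissues for c in design.cultivars]


def make_truth(
    lib: SuspectLibrary,
    design: StudyDesign = StudyDesign(),
    family_shares: dict[str, dict[str, float]] | None = None,
    glyco_shares: dict[str, dict[str, float]] | None = None,
    leaf_root_ratios: dict[str, float] | None = None,
    root_total: float = 1e6,
    effects: dict[str, dict[tuple[str, str], float]] | None = None,
    biological_sd: float = 0.25,
    technical_sd: float = 0.15,
    name: str = "custom",
) -> SimulationTruth:
    """Build baselines that honour composition targets by construction.

    Each tissue's total intensity (``root_total``, scaled by the leaf/root
    ratio for leaf samples) is split across composition categories per the
    share targets (families by default, glycosylation classes when
    ``glyco_shares`` is given) and equally among the compounds of each
    category, then converted to log2 baselines.
    """
    if family_shares is not None and glyco_shares is not None:
        raise ValueError("give family_shares or glyco_shares, not both")
    shares = glyco_shares if glyco_shares is not None else (
        family_shares if family_shares is not None else DEFAULT_FAMILY_SHARES
    )
    by_glyco = glyco_shares is not None
    ratios = dict(leaf_root_ratios or DEFAULT_LEAF_ROOT_RATIOS)

    def category(comp) -> str:
        return classify_glyco(comp)[0] if by_glyco else comp.family

    compounds = [c.name for c in lib.compounds]
    members: dict[str, list[str]] = {}
    for c in lib.compounds:
        members.setdefault(category(c), []).append(c.name)

    cols = _group_columns(design)
    base = pd.DataFrame(0.0, index=compounds, columns=pd.MultiIndex.from_tuples(cols))
    for tissue, cultivar in cols:
        tissue_shares = shares.get(tissue)
        if tissue_shares is None:
            raise ValueError(f"no composition shares for tissue {tissue!r}")
        total = root_total * ratios.get(cultivar, 1.0) if tissue == "leaf" else root_total
        for cat, frac in tissue_shares.items():
            group = members.get(cat, [])
            if not group:
                continue
            per_compound = frac * total / len(group)
            for name_ in group:
                base.loc[name_, (tissue, cultivar)] = np.log2(per_compound)

    eff = pd.DataFrame(0.0, index=compounds, columns=base.columns)
    for comp_name, entry in (effects or {}).items():
        if comp_name not in eff.index:
            raise ValueError(f"effect for unknown compound {comp_name!r}")
        for (tissue, cultivar), val in entry.items():
            eff.loc[comp_name, (tissue, cultivar)] = val

    return SimulationTruth(base, eff, biological_sd, technical_sd, name=name)


def paper_like_truth(lib: SuspectLibrary, design: StudyDesign = StudyDesign()) -> SimulationTruth:
    """The differential preset: composition targets plus the published-style
    per-compound treatment effects as ground truth."""
    return make_truth(
        lib,
        design,
        effects=TREATMENT_EFFECTS_LOG2FC,
        name="paper-like",
    )


def null_truth(lib: SuspectLibrary, design: StudyDesign = StudyDesign()) -> SimulationTruth:
    """All treatment effects zero (type-I error control checks)."""
    return make_truth(lib, design, effects={}, name="null")


# ---------------------------------------------------------------------------
# intensities


def generate_intensities(
    design: StudyDesign,
    truth: SimulationTruth,
    seed: int | None = None,
) -> IntensityMatrix:
    """Draw a log-normal intensity matrix for the full design.

    log2 intensity = baseline + effect (Hg arm only)
    + Normal(0, biological SD) shared by the injections of one biological
    replicate + Normal(0, technical SD) per injection; exponentiated to the
    linear scale.
    """
    for tissue, cultivar in _group_columns(design):
        if (tissue, cultivar) not in truth.baselines.columns:
            raise ValueError(f"truth does not cover group {(tissue, cultivar)}")
    rng = np.random.default_rng(seed)
    meta = design.sample_table()
    compounds = list(truth.baselines.index)
    n_comp = len(compounds)

    values = np.zeros((len(meta), n_comp))
    bio_noise: dict[tuple, np.ndarray] = {}
    for row_i, (sid, row) in enumerate(meta.iterrows()):
        key = (row.cultivar, row.tissue, row.treatment, row.replicate)
        if key not in bio_noise:
            bio_noise[key] = rng.normal(0.0, truth.biological_sd, n_comp)
        log2i = truth.baselines[(row.tissue, row.cultivar)].to_numpy(float).copy()
        if row.treatment != design.treatments[0]:
            log2i = log2i + truth.effects[(row.tissue, row.cultivar)].to_numpy(float)
        log2i = log2i + bio_noise[key]
        if truth.technical_sd > 0:
            log2i = log2i + rng.normal(0.0, truth.technical_sd, n_comp)
        values[row_i] = np.exp2(log2i)

    frame = pd.DataFrame(values, index=meta.index, columns=compounds)
    return IntensityMatrix(frame, meta)


# ---------------------------------------------------------------------------
# ground-truth reporting


def truth_report(truth: SimulationTruth) -> pd.DataFrame:
    """Long-format table of baselines and true effects, one row per
    compound x tissue x cultivar."""
    rows = []
    for comp in truth.baselines.index:
        for tissue, cultivar in truth.baselines.columns:
            rows.append(
                {
                    "compound": comp,
                    "tissue": tissue,
                    "cultivar": cultivar,
                    "baseline_log2": float(truth.baselines.loc[comp, (tissue, cultivar)]),
                    "effect_log2fc": float(truth.effects.loc[comp, (tissue, cultivar)]),
                }
            )
    return pd.DataFrame(rows)


def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    truth_report(truth).to_csv(path, index=False)


def read_truth(
    path: str | Path, biological_sd: float = 0.25, technical_sd: float = 0.15
) -> SimulationTruth:
    df = pd.read_csv(path)
    base = df.pivot(index="compound", columns=["tissue", "cultivar"], values="baseline_log2")
    eff = df.pivot(index="compound", columns=["tissue", "cultivar"], values="effect_log2fc")
    # preserve original compound order
    order = df["compound"].drop_duplicates().tolist()
    return SimulationTruth(
        base.loc[order], eff.loc[order], biological_sd, technical_sd
    )
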