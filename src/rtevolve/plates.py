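"""Synthetic viability-plate generator for the screening stage.

Emulates 96-well MTT/OD570 measurements over a Gemcitabine concentration
grid: each well's expected signal follows a log-logistic viability curve for
the clone's genotype, plus seeded Gaussian noise truncated at zero.

Genotype model. Ordinary library clones carry transgenes that are mostly
neutral or inactivating, so they respond like the untransduced control
(baseline IC50). The wild-type-transgene control overexpresses the functional
kinase, activates more prodrug, and therefore sits at a *lower* IC50 — this
is what creates the margin that the replicate-wise hit rule (death above both
controls) needs to keep false positives near zero. Designated "sensitizer"
clones have the baseline IC50 divided by the configured fold.

Two canonical scenarios are provided: a 76-clone primary screen with
implanted sensitizers, and a three-population sensitization panel in which
the untransduced/test IC50 ratio is 300 and the wild-type/test ratio is 60.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Collection, Iterable, Mapping

import numpy as np
import pandas as pd

from .core import CloneRecord
from .screening import ViabilityPlate

SensitizerSpec = Collection[str] | Callable[[str], bool]


@dataclass(frozen=True)
class PlateParams:
    """Generator parameters for synthetic viability plates.

    Defaults describe a primary screen at 10 nM prodrug: library clones at a
    baseline IC50 of 150 nM, the wild-type-transgene control at 40 nM (it
    activates more prodrug than the mostly-inactive library variants), and
    sensitizers 60-fold below baseline. Noise is additive on the OD signal
    (scale of a baseline signal of 1).
    """

    baseline_ic50: float = 150.0        # nM, ordinary library clones
    hill: float = 1.5
    sensitizer_fold: float = 60.0       # sensitizer IC50 = baseline / fold
    noise_sd: float = 0.02              # OD-scale Gaussian noise
    baseline_signal: float = 1.0
    untransduced_ic50: float | None = None   # default: baseline_ic50
    wt_control_ic50: float | None = 40.0
    sensitizers: SensitizerSpec = field(default_factory=frozenset)

    def is_sensitizer(self, clone_id: str) -> bool:
        if callable(self.sensitizers):
            return bool(self.sensitizers(clone_id))
        return clone_id in self.sensitizers

    def ic50_for(self, clone_id: str,
                 control_ids: tuple[str, str] = ("untransduced", "wt-dCK")) -> float:
        if clone_id == control_ids[0]:
            return self.untransduced_ic50 if self.untransduced_ic50 is not None else self.baseline_ic50
        if clone_id == control_ids[1]:
            return self.wt_control_ic50 if self.wt_control_ic50 is not None else self.baseline_ic50
        if self.is_sensitizer(clone_id):
            return self.baseline_ic50 / self.sensitizer_fold
        return self.baseline_ic50


def _plate_from_ic50_map(ic50_by_id: Mapping[str, float], concentrations,
                         hill: float, noise_sd: float, n_experiments: int,
                         *, seed: int, baseline_signal: float = 1.0) -> ViabilityPlate:
    conc = np.asarray(concentrations, dtype=float)
    if (conc < 0).any():
        raise ValueError("concentrations must be non-negative")
    if not (conc == 0).any():
        raise ValueError("the concentration grid must include 0 (death rates need it)")
    rng = np.random.default_rng(seed)
    ids = list(ic50_by_id)
    ic50s = np.array([ic50_by_id[i] for i in ids], dtype=float)
    if (ic50s <= 0).any():
        raise ValueError("IC50s must be positive")
    ratio = np.zeros((len(ids), conc.size))
    pos = conc > 0
    ratio[:, pos] = (conc[None, pos] / ic50s[:, None]) ** hill
    signal = baseline_signal / (1.0 + ratio)
    rows = []
    for e in range(1, n_experiments + 1):
        noisy = signal + (rng.normal(0.0, noise_sd, size=signal.shape)
                          if noise_sd > 0 else 0.0)
        noisy = np.clip(noisy, 0.0, None)
        for i, cid in enumerate(ids):
            for j, c in enumerate(conc):
                rows.append((cid, f"exp{e}", float(c), float(noisy[i, j])))
    df = pd.DataFrame(rows, columns=["clone_id", "experiment_id",
                                     "concentration_nM", "readout"])
    return ViabilityPlate(df)


def generate_viability_plate(library: Iterable[CloneRecord | str], concentrations,
                             params: PlateParams, *, seed: int,
                             n_experiments: int = 3,
                             control_ids: tuple[str, str] | None = ("untransduced", "wt-dCK"),
                             ) -> ViabilityPlate:
    """Generate a synthetic screen for the given clones.

    ``library`` may be simulated CloneRecords or bare clone ids; controls are
    appended unless ``control_ids`` is None. Deterministic given ``seed``.
    """
    ids = [c.clone_id if isinstance(c, CloneRecord) else str(c) for c in library]
    if not ids:
        raise ValueError("empty library")
    ctrl = control_ids or ("untransduced", "wt-dCK")
    ic50_by_id = {cid: params.ic50_for(cid, ctrl) for cid in ids}
    if control_ids is not None:
        for c in control_ids:
            ic50_by_id[c] = params.ic50_for(c, control_ids)
    return _plate_from_ic50_map(
        ic50_by_id, concentrations, params.hill, params.noise_sd, n_experiments,
        seed=seed, baseline_signal=params.baseline_signal,
    )


def screening_scenario(*, seed: int, n_clones: int = 76, n_sensitizers: int = 6,
                       n_experiments: int = 3, params: PlateParams | None = None,
                       concentrations=(0.0, 10.0, 35.0, 70.0),
                       ) -> tuple[ViabilityPlate, tuple[str, ...]]:
    """Primary screen: n_clones library clones with implanted sensitizers.

    Returns the plate and the implant log (the ids of the true sensitizers),
    against which downstream hit calling can be scored.
    """
    rng = np.random.default_rng(seed)
    width = len(str(n_clones))
    ids = [f"clone{i:0{width}d}" for i in range(1, n_clones + 1)]
    implanted = tuple(sorted(str(c) for c in rng.choice(ids, size=n_sensitizers, replace=False)))
    base = params or PlateParams()
    full = PlateParams(
        baseline_ic50=base.baseline_ic50, hill=base.hill,
        sensitizer_fold=base.sensitizer_fold, noise_sd=base.noise_sd,
        baseline_signal=base.baseline_signal,
        untransduced_ic50=base.untransduced_ic50,
        wt_control_ic50=base.wt_control_ic50,
        sensitizers=frozenset(implanted),
    )
    plate = generate_viability_plate(
        ids, concentrations, full, seed=int(rng.integers(2 ** 31)),
        n_experiments=n_experiments,
    )
    return plate, implanted


def sensitization_scenario(*, seed: int, noise_sd: float = 0.0,
                           ic50_test: float = 75.0, fold_wt: float = 60.0,
                           fold_untransduced: float = 300.0, hill: float = 1.5,
                           n_experiments: int = 1) -> ViabilityPlate:
    """Three-population dose-response panel for fold-change recovery.

    Defaults place the sensitized population at IC50 75 nM, the wild-type
    transgene 60-fold above it (4.5 uM) and untransduced cells 300-fold above
    it (22.5 uM) — the canonical sensitization pattern of a resistant line.
    The grid spans 1 nM to 100 uM plus the 0 reference.
    """
    ic50_by_id = {
        "untransduced": ic50_test * fold_untransduced,
        "wt-dCK": ic50_test * fold_wt,
        "sensitizer": ic50_test,
    }
    conc = np.concatenate([[0.0], np.geomspace(1.0, 1e5, 12)])
    return _plate_from_ic50_map(ic50_by_id, conc, hill, noise_sd, n_experiments,
                                seed=seed)
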