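"""Model space construction and fixed-effects Bayesian model selection.

Sixteen bilinear models: two input families (PMC-input = models 1-8,
SMA-input = models 9-16; model 8+j shares model j's modulatory structure).
All models share the intrinsic coupling core and modulate the motor triangle
(PMC<->SMA, PMC<->M1, SMA<->M1); the eight structures per family are
enumerated by three binary toggles: modulation of DLPFC->PMC, modulation of
DLPFC->SMA, and the identity of the return edge to DLPFC (PMC->DLPFC vs
SMA->DLPFC).  Family priors are uniform (1/K) and model priors 1/(K N_k), so
family posteriors are the subset sums of model posteriors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .dcm_core import NODE_INDEX, DCMFit, DCMSpec
from .errors import DegenerateEvidenceError, InvalidInputError

FAMILY_NAMES = ("PMC_input", "SMA_input")

#: default within-family structures: (modulate DLPFC->PMC, modulate
#: DLPFC->SMA, return edge to DLPFC).  Replaceable by user-supplied layouts.
DEFAULT_STRUCTURES = tuple(
    (bool(t1), bool(t2), "SMA" if t3 else "PMC")
    for t1 in (0, 1)
    for t2 in (0, 1)
    for t3 in (0, 1)
)

_CORE_B_EDGES = [
    ("SMA", "PMC"), ("PMC", "SMA"),
    ("M1", "PMC"), ("PMC", "M1"),
    ("M1", "SMA"), ("SMA", "M1"),
]


def _shared_a_mask() -> np.ndarray:
    a = np.ones((4, 4), bool)
    np.fill_diagonal(a, False)
    a[NODE_INDEX["M1"], NODE_INDEX["DLPFC"]] = False
    a[NODE_INDEX["DLPFC"], NODE_INDEX["M1"]] = False
    return a


def _b_mask(structure) -> np.ndarray:
    mod_dlpfc_pmc, mod_dlpfc_sma, return_src = structure
    b = np.zeros((4, 4), bool)
    for tgt, src in _CORE_B_EDGES:
        b[NODE_INDEX[tgt], NODE_INDEX[src]] = True
    if mod_dlpfc_pmc:
        b[NODE_INDEX["PMC"], NODE_INDEX["DLPFC"]] = True
    if mod_dlpfc_sma:
        b[NODE_INDEX["SMA"], NODE_INDEX["DLPFC"]] = True
    b[NODE_INDEX["DLPFC"], NODE_INDEX[return_src]] = True
    return b


@dataclass(frozen=True)
class ModelSpace:
    models: tuple  # of DCMSpec, ordered by model index 1..16
    family_of: dict  # model index -> family name

    def __len__(self):
        return len(self.models)

    def model(self, index: int) -> DCMSpec:
        return self.models[index - 1]

    def family_members(self, family: str) -> list[int]:
        return [i for i, f in self.family_of.items() if f == family]


def build_model_space(structures=DEFAULT_STRUCTURES) -> ModelSpace:
    """2 input families x 8 modulatory structures -> 16 models."""
    if len(structures) != 8:
        raise InvalidInputError("exactly 8 within-family structures required")
    a = _shared_a_mask()
    models, family_of = [], {}
    for fam_i, (fam, region) in enumerate(zip(FAMILY_NAMES, ("PMC", "SMA"))):
        c = np.zeros(4, bool)
        c[NODE_INDEX[region]] = True
        for j, st in enumerate(structures, start=1):
            idx = fam_i * 8 + j
            models.append(
                DCMSpec(a_mask=a, b_mask=_b_mask(st), c_mask=c, name=f"model_{idx}")
            )
            family_of[idx] = fam
    return ModelSpace(models=tuple(models), family_of=family_of)


@dataclass(frozen=True)
class FamilyPartition:
    families: dict  # family name -> tuple of model indices

    @property
    def K(self) -> int:
        return len(self.families)

    @property
    def n_models(self) -> int:
        return sum(len(v) for v in self.families.values())

    def family_prior(self, family: str) -> float:
        return 1.0 / self.K

    def model_prior(self, index: int) -> float:
        for members in self.families.values():
            if index in members:
                return 1.0 / (self.K * len(members))
        raise InvalidInputError(f"model {index} not in any family")

    def model_priors(self) -> np.ndarray:
        return np.array([self.model_prior(i) for i in sorted(self._all())])

    def _all(self):
        return [i for v in self.families.values() for i in v]

    def __post_init__(self):
        seen = self._all()
        if len(seen) != len(set(seen)):
            raise InvalidInputError("families must be disjoint")


def default_partition(space: ModelSpace | None = None) -> FamilyPartition:
    space = space or build_model_space()
    return FamilyPartition(
        families={f: tuple(space.family_members(f)) for f in FAMILY_NAMES}
    )


@dataclass
class EvidenceTable:
    F: np.ndarray  # (n_subjects, n_models) free energies, nats
    subject_ids: tuple
    stream: str = ""  # e.g. "ME_correct"

    def __post_init__(self):
        self.F = np.asarray(self.F, float)
        if self.F.ndim != 2 or self.F.shape[0] != len(self.subject_ids):
            raise InvalidInputError("one evidence row per subject required")
        if not np.all(np.isfinite(self.F)):
            raise InvalidInputError("evidence entries must be finite")


@dataclass
class BMSResult:
    summed_log_evidence: np.ndarray  # per model, nats
    model_posteriors: np.ndarray  # p(m | Y)
    family_posteriors: dict  # family -> p(f_k | Y)
    dominant_family: str
    best_model_index: int
    within_family_posteriors: np.ndarray  # over the dominant family's 8 models
    bma_couplings: np.ndarray | None = None  # 4x4 averaged B (row=target)


def ffx_pool(evidence: EvidenceTable) -> np.ndarray:
    """Fixed-effects pooling: the vector of summed log evidences per model."""
    if evidence.F.shape[0] < 1:
        raise InvalidInputError("at least one subject required")
    return evidence.F.sum(axis=0)


def model_posteriors(summed_F: np.ndarray, partition: FamilyPartition) -> np.ndarray:
    """p(m|Y) proportional to exp(F_m) p(m), normalized in log space."""
    summed_F = np.asarray(summed_F, float)
    if len(summed_F) != partition.n_models:
        raise InvalidInputError("evidence length must match the partition")
    if np.all(np.isneginf(summed_F)):
        raise DegenerateEvidenceError("all model evidences are -inf")
    logp = summed_F + np.log(partition.model_priors())
    return np.exp(logp - logsumexp(logp))


def family_posteriors(p_m_given_y: np.ndarray, partition: FamilyPartition):
    """Subset sums of model posteriors; returns ({family: p}, dominant)."""
    p = np.asarray(p_m_given_y, float)
    if abs(p.sum() - 1.0) > 1e-8:
        raise InvalidInputError("model posteriors must be normalized")
    fams = {
        fam: float(sum(p[i - 1] for i in members))
        for fam, members in partition.families.items()
    }
    dominant = max(fams, key=fams.get)
    return fams, dominant


def restrict_and_select(summed_F: np.ndarray, partition: FamilyPartition, family: str):
    """FFX posteriors over the dominant family only (uniform prior within);
    returns (best model index, within-family posterior vector)."""
    members = sorted(partition.families[family])
    F_sub = np.asarray(summed_F, float)[[i - 1 for i in members]]
    logp = F_sub - logsumexp(F_sub)  # uniform prior cancels
    p = np.exp(logp)
    best = members[int(np.argmax(F_sub))]  # argmax picks the lowest index on ties
    return best, p


def bma_couplings(
    fits: dict, posteriors: np.ndarray, space: ModelSpace, members=None
) -> np.ndarray:
    """Posterior-weighted mean of posterior-mean B matrices over ``members``.

    ``fits``: model index -> DCMFit.  Absent edges contribute zero.
    """
    members = sorted(members if members is not None else fits)
    if len(posteriors) != len(members):
        raise InvalidInputError("one posterior weight per model required")
    out = np.zeros((4, 4))
    for w, idx in zip(posteriors, members):
        fit: DCMFit = fits[idx]
        out += w * fit.posterior_b_matrix(space.model(idx))
    return out


def run_bms(
    evidence: EvidenceTable,
    partition: FamilyPartition | None = None,
    fits: dict | None = None,
    space: ModelSpace | None = None,
) -> BMSResult:
    """FFX pooling -> family inference -> within-family selection (-> BMA)."""
    partition = partition or default_partition(space)
    summed = ffx_pool(evidence)
    p_m = model_posteriors(summed, partition)
    fams, dominant = family_posteriors(p_m, partition)
    best, p_within = restrict_and_select(summed, partition, dominant)
    bma = None
    if fits is not None:
        space = space or build_model_space()
        members = sorted(partition.families[dominant])
        bma = bma_couplings(fits, p_within, space, members)
    return BMSResult(
        summed_log_evidence=summed,
        model_posteriors=p_m,
        family_posteriors=fams,
        dominant_family=dominant,
        best_model_index=best,
        within_family_posteriors=p_within,
        bma_couplings=bma,
    )
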