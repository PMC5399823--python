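"""Synthetic MSAP experiments with known methylation dynamics.

The simulator emulates the data-generating situation of a paired
control/stress MSAP design: every marker corresponds to one CCGG
restriction site per sample, the control site state is drawn from a
configurable distribution over the six admissible states, and stress
perturbs each cytosine independently — a methylated position demethylates
with the context-specific rate ``p_dm_*``, an unmethylated one gains
methylation with ``p_dnm_*`` (external positions are CHG context, internal
ones CG).  Proposals leaving the admissible state space (up to the
strand-symmetry convention) are redrawn for that site, and the rejection
rate is recorded.  The realised per-position events are the ground truth
against which the code-count quantification can be compared.

The simulator deliberately omits AFLP selective-primer sampling,
fragment-length effects, co-migration and band-intensity variation: it
produces ideal binary tracks implied by the digestion model.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .profiles_io import ExperimentBundle, MarkerMatrix
from .site_model import (
    ADMISSIBLE_PATTERNS,
    STATE_ORDER,
    SiteState,
    canonical_state,
    digest_profile,
)

__all__ = ["SimulationConfig", "SimulatedTruth", "simulate", "recovery_report"]

_TRUTH_COLUMNS = ("DM", "DNM", "MSP", "NMSP",
                  "DM-CG", "DM-CHG", "DNM-CG", "DNM-CHG")


def _uniform_probs() -> dict[str, float]:
    return {s.name: 1.0 / 6.0 for s in STATE_ORDER}


@dataclass
class SimulationConfig:
    """Parameters of a synthetic paired control/stress MSAP experiment.

    Defaults mirror a realistic cereal experiment: on the order of 900
    scoreable fragments per line, ten lines, demethylation exceeding de
    novo methylation and CG-context change roughly threefold the CHG rate.
    The control-state distribution defaults to uniform over the six
    admissible states, as no empirical frequencies are established.
    """

    n_markers: int = 880
    n_samples: int = 10
    control_state_probs: dict[str, float] = field(default_factory=_uniform_probs)
    p_dm_cg: float = 0.05
    p_dm_chg: float = 0.015
    p_dnm_cg: float = 0.015
    p_dnm_chg: float = 0.005
    seed: int = 0

    def validate(self) -> None:
        if self.n_markers < 1 or self.n_samples < 1:
            raise ValueError("n_markers and n_samples must be positive")
        for name in ("p_dm_cg", "p_dm_chg", "p_dnm_cg", "p_dnm_chg"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        probs = np.array([self.control_state_probs.get(s.name, 0.0)
                          for s in STATE_ORDER], dtype=float)
        if (probs < 0).any():
            raise ValueError("control_state_probs must be non-negative")
        unknown = set(self.control_state_probs) - {s.name for s in STATE_ORDER}
        if unknown:
            raise ValueError(f"unknown states in control_state_probs: {unknown}")
        if abs(probs.sum() - 1.0) > 1e-12:
            raise ValueError("control_state_probs must sum to 1")

    def state_prob_vector(self) -> np.ndarray:
        return np.array([self.control_state_probs.get(s.name, 0.0)
                         for s in STATE_ORDER], dtype=float)


@dataclass
class SimulatedTruth:
    """A simulated bundle together with its realised event counts."""

    config: SimulationConfig
    bundle: ExperimentBundle
    events: pd.DataFrame  #: samples x event columns, realised counts
    rejection_rate: float  #: fraction of site proposals redrawn

    @property
    def event_fractions(self) -> pd.DataFrame:
        """Realised events as percentages of the 4 * n_markers positions."""
        return 100.0 * self.events / (4.0 * self.config.n_markers)


def _propose(control_bits: np.ndarray, rng: np.random.Generator,
             p_dm: np.ndarray, p_dnm: np.ndarray) -> np.ndarray:
    """One stress proposal per site: independent per-position flips."""
    u = rng.random(control_bits.shape)
    flip_down = (control_bits == 1) & (u < p_dm)
    flip_up = (control_bits == 0) & (u < p_dnm)
    return np.where(flip_down, 0, np.where(flip_up, 1, control_bits))


def simulate(config: SimulationConfig) -> SimulatedTruth:
    """Run the simulation; deterministic under ``config.seed``.

    Stressed configurations are produced by rejection sampling: a site's
    per-position flip proposal is redrawn (for that site only) until the
    result lies in the admissible state space.  Mirror patterns of the
    hemimethylated states count as admissible and are canonicalised, since
    the state set does not distinguish which strand carries the mark.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n_sites = config.n_markers * config.n_samples

    state_lookup = np.array([s.value for s in STATE_ORDER], dtype=np.int8)
    control_idx = rng.choice(len(STATE_ORDER), size=n_sites,
                             p=config.state_prob_vector())
    control = state_lookup[control_idx]  # n_sites x 4

    # per-position rates: external (CHG) positions 0-1, internal (CG) 2-3
    p_dm = np.array([config.p_dm_chg, config.p_dm_chg,
                     config.p_dm_cg, config.p_dm_cg])
    p_dnm = np.array([config.p_dnm_chg, config.p_dnm_chg,
                      config.p_dnm_cg, config.p_dnm_cg])

    admissible = np.zeros(16, dtype=bool)
    for pat in ADMISSIBLE_PATTERNS:
        admissible[pat[0] * 8 + pat[1] * 4 + pat[2] * 2 + pat[3]] = True

    stressed = np.empty_like(control)
    pending = np.arange(n_sites)
    n_rejected = 0
    while pending.size:
        prop = _propose(control[pending], rng, p_dm, p_dnm)
        code = prop @ np.array([8, 4, 2, 1])
        ok = admissible[code]
        stressed[pending[ok]] = prop[ok]
        n_rejected += int((~ok).sum())
        pending = pending[~ok]
    rejection_rate = n_rejected / (n_rejected + n_sites)

    # realised per-position events, before canonicalising mirrors
    meth_before = control == 1
    meth_after = stressed == 1
    ext = np.array([True, True, False, False])
    ev = {}
    dm_pos = meth_before & ~meth_after
    dnm_pos = ~meth_before & meth_after
    ev["DM-CHG"] = dm_pos[:, ext]
    ev["DM-CG"] = dm_pos[:, ~ext]
    ev["DNM-CHG"] = dnm_pos[:, ext]
    ev["DNM-CG"] = dnm_pos[:, ~ext]
    ev["MSP"] = meth_before & meth_after
    ev["NMSP"] = ~meth_before & ~meth_after

    sample_of_site = np.repeat(np.arange(config.n_samples), config.n_markers)
    sample_ids = [f"S{i + 1}" for i in range(config.n_samples)]
    events = pd.DataFrame(0, index=sample_ids, columns=list(_TRUTH_COLUMNS),
                          dtype=np.int64)
    for name, mask in ev.items():
        per_site = mask.sum(axis=1)
        events[name] = np.bincount(sample_of_site, weights=per_site,
                                   minlength=config.n_samples).astype(np.int64)
    events["DM"] = events["DM-CG"] + events["DM-CHG"]
    events["DNM"] = events["DNM-CG"] + events["DNM-CHG"]
    events = events[list(_TRUTH_COLUMNS)]
    events.index.name = "sample"

    # canonicalise and digest
    stressed_states = [canonical_state(row) for row in stressed]
    control_states = [SiteState(tuple(row)) for row in control]
    tracks = {name: np.empty((config.n_markers, config.n_samples))
              for name in ("control_hpa", "control_msp",
                           "stressed_hpa", "stressed_msp")}
    c_prof = np.array([digest_profile(s) for s in control_states])
    s_prof = np.array([digest_profile(s) for s in stressed_states])
    shape = (config.n_samples, config.n_markers)
    tracks["control_hpa"] = c_prof[:, 0].reshape(shape).T
    tracks["control_msp"] = c_prof[:, 1].reshape(shape).T
    tracks["stressed_hpa"] = s_prof[:, 0].reshape(shape).T
    tracks["stressed_msp"] = s_prof[:, 1].reshape(shape).T

    marker_ids = [f"M{i + 1}" for i in range(config.n_markers)]
    bundle = ExperimentBundle(**{
        name: MarkerMatrix(pd.DataFrame(arr, index=marker_ids,
                                        columns=sample_ids, dtype=float))
        for name, arr in tracks.items()
    })
    return SimulatedTruth(config=config, bundle=bundle, events=events,
                          rejection_rate=rejection_rate)


def recovery_report(truth: SimulatedTruth,
                    estimated: pd.DataFrame) -> pd.DataFrame:
    """Tabulate realised event fractions against estimated percentages.

    ``estimated`` is a characteristics table computed on the simulated
    bundle.  Returns a long-format DataFrame with columns ``sample``,
    ``characteristic``, ``realized_pct``, ``estimated_pct``.  The estimate
    need not be unbiased — the equal-probability weighting has an intrinsic
    baseline for ambiguous codes — but it should co-vary with the truth.
    """
    realized = truth.event_fractions
    if list(estimated.index) != list(realized.index):
        raise ValueError(
            f"sample mismatch: truth has {list(realized.index)}, "
            f"estimate has {list(estimated.index)}"
        )
    rows = []
    for name in _TRUTH_COLUMNS:
        est_col = f"{name}%"
        for sample in realized.index:
            rows.append({
                "sample": sample,
                "characteristic": name,
                "realized_pct": realized.loc[sample, name],
                "estimated_pct": estimated.loc[sample, est_col],
            })
    return pd.DataFrame(rows)
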