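"""Vectorised population prediction engine.

A :class:`Design` flattens a dataset into (observation, dose) contribution
pairs per analyte, so that concentrations for the whole population - and for
whole stacks of simulation replicates - are computed in a handful of numpy
passes.  This is the workhorse behind FOCEI estimation, covariate search and
NPDE simulation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .data import ANALYTE_NAME, DVID_ODV, DVID_VEN, Dataset, build_subject
from .model import (
    dose_pairs,
    metabolite_conc_pairs,
    parent_conc_pairs,
)


@dataclass
class _PairBlock:
    obs: np.ndarray  # (n_pairs,) observation index
    sub: np.ndarray  # (n_pairs,) subject index
    dose: np.ndarray
    dt: np.ndarray
    tau: np.ndarray
    agg: sp.csr_matrix  # (n_obs, n_pairs)


@dataclass
class Design:
    """Flattened population design for batched prediction.

    Observations are stored contiguously per subject (parent first, then
    metabolite, each time-ordered).  Observations whose model prediction is
    structurally zero (e.g. a pre-dose sample) carry no information under a
    proportional residual model and are dropped with a record of how many.
    """

    subject_ids: np.ndarray
    obs_subject: np.ndarray
    obs_dvid: np.ndarray
    obs_time: np.ndarray
    obs_tad: np.ndarray
    y: np.ndarray
    subject_slices: list[slice]
    pairs: dict[int, _PairBlock]
    cov: dict[str, np.ndarray]
    n_dropped_structural_zero: int
    skipped_subjects: list[int] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_obs(self) -> int:
        return len(self.y)

    @classmethod
    def from_dataset(cls, dataset: Dataset) -> "Design":
        obs_subject: list[int] = []
        obs_dvid: list[int] = []
        obs_time: list[float] = []
        obs_tad: list[float] = []
        y: list[float] = []
        slices: list[slice] = []
        cov_rows: list[dict[str, float]] = []
        kept_ids: list[int] = []
        skipped: list[int] = []
        pair_parts: dict[int, list[tuple]] = {DVID_VEN: [], DVID_ODV: []}
        n_dropped = 0

        s_index = -1
        for sid in dataset.subject_ids:
            sub = build_subject(dataset, sid)
            start = len(y)
            sub_kept = 0
            staged: dict[int, tuple] = {}
            ev_times = np.array([e.time for e in sub.regimen.doses])
            for dvid, name in ANALYTE_NAME.items():
                times = sub.times[name]
                if times.size == 0:
                    continue
                p_obs, p_dose, p_dt, p_tau, p_ev = dose_pairs(sub.regimen, times)
                # occasions: each observation is attributed to its most
                # recent dose event only (full washout between events,
                # no carryover term)
                occ = np.searchsorted(ev_times, times, side="right") - 1
                live = ((p_dt > 0.0) | np.isfinite(p_tau)) & (p_ev == occ[p_obs])
                informative = np.zeros(times.size, dtype=bool)
                np.add.at(informative, p_obs[live], True)
                n_dropped += int((~informative).sum())
                if not informative.any():
                    continue
                remap = -np.ones(times.size, dtype=int)
                remap[informative] = np.arange(informative.sum())
                keep_pairs = informative[p_obs] & live
                staged[dvid] = (
                    times[informative],
                    sub.dv[name][informative],
                    remap[p_obs[keep_pairs]],
                    p_dose[keep_pairs],
                    p_dt[keep_pairs],
                    p_tau[keep_pairs],
                )
            if not staged:
                skipped.append(int(sid))
                continue
            s_index += 1
            kept_ids.append(int(sid))
            cov_rows.append(sub.covariates.as_dict())
            for dvid, (t_keep, dv_keep, p_obs, p_dose, p_dt, p_tau) in staged.items():
                base = len(y)
                obs_subject.extend([s_index] * len(t_keep))
                obs_dvid.extend([dvid] * len(t_keep))
                obs_time.extend(t_keep.tolist())
                y.extend(dv_keep.tolist())
                tad = np.full(len(t_keep), np.inf)
                np.minimum.at(tad, p_obs, p_dt)
                obs_tad.extend(tad.tolist())
                pair_parts[dvid].append(
                    (p_obs + base, np.full(len(p_obs), s_index), p_dose, p_dt, p_tau)
                )
                sub_kept += len(t_keep)
            slices.append(slice(start, start + sub_kept))

        n_obs = len(y)
        pairs: dict[int, _PairBlock] = {}
        for dvid, parts in pair_parts.items():
            if not parts:
                continue
            p_obs = np.concatenate([p[0] for p in parts])
            p_sub = np.concatenate([p[1] for p in parts])
            p_dose = np.concatenate([p[2] for p in parts])
            p_dt = np.concatenate([p[3] for p in parts])
            p_tau = np.concatenate([p[4] for p in parts])
            agg = sp.csr_matrix(
                (np.ones(len(p_obs)), (p_obs, np.arange(len(p_obs)))),
                shape=(n_obs, len(p_obs)),
            )
            pairs[dvid] = _PairBlock(p_obs, p_sub, p_dose, p_dt, p_tau, agg)

        cov = {
            name: np.array([row[name] for row in cov_rows], dtype=float)
            for name in (cov_rows[0] if cov_rows else {})
        }
        return cls(
            subject_ids=np.array(kept_ids),
            obs_subject=np.array(obs_subject, dtype=int),
            obs_dvid=np.array(obs_dvid, dtype=int),
            obs_time=np.array(obs_time, dtype=float),
            obs_tad=np.array(obs_tad, dtype=float),
            y=np.array(y, dtype=float),
            subject_slices=slices,
            pairs=pairs,
            cov=cov,
            n_dropped_structural_zero=n_dropped,
            skipped_subjects=skipped,
        )

    def predict(self, cl, v, clm, vm, ka, fp) -> np.ndarray:
        """Concentrations for every retained observation.

        Each parameter is an array whose last axis indexes subjects; any
        leading axes (e.g. simulation replicates) broadcast through.
        Returns shape ``leading + (n_obs,)``.
        """
        cl, v, clm, vm, ka, fp = np.broadcast_arrays(
            *(np.asarray(a, dtype=float) for a in (cl, v, clm, vm, ka, fp))
        )
        kp = cl / v
        km = clm / vm
        lead = cl.shape[:-1]
        out = np.zeros(lead + (self.n_obs,))
        for dvid, p in self.pairs.items():
            if dvid == DVID_VEN:
                c = parent_conc_pairs(
                    p.dose, p.dt, p.tau, ka[..., p.sub], kp[..., p.sub],
                    fp[..., p.sub], v[..., p.sub],
                )
            else:
                c = metabolite_conc_pairs(
                    p.dose, p.dt, p.tau, ka[..., p.sub], kp[..., p.sub],
                    km[..., p.sub], fp[..., p.sub], vm[..., p.sub],
                )
            flat = c.reshape(-1, c.shape[-1])
            acc = (p.agg @ flat.T).T.reshape(lead + (self.n_obs,))
            out += acc
        return out

    def sigma2_per_obs(self, sigma2_ven: float, sigma2_odv: float) -> np.ndarray:
        return np.where(self.obs_dvid == DVID_VEN, sigma2_ven, sigma2_odv)

    def tile(self, b: int) -> "Design":
        """Replicate the whole design ``b`` times as disjoint subject blocks.

        Used to evaluate the population objective at ``b`` parameter vectors
        in one vectorised pass (finite-difference gradients, Hessian
        blocks): block ``i`` holds virtual copies of every subject that can
        carry its own parameter configuration.  Results are cached on the
        instance per ``b``.
        """
        cache = getattr(self, "_tile_cache", None)
        if cache is None:
            cache = self._tile_cache = {}
        if b in cache:
            return cache[b]
        S, n = self.n_subjects, self.n_obs
        slices = []
        for i in range(b):
            for sl in self.subject_slices:
                slices.append(slice(sl.start + i * n, sl.stop + i * n))
        pairs = {}
        for dvid, p in self.pairs.items():
            np_ = len(p.obs)
            pairs[dvid] = _PairBlock(
                obs=np.concatenate([p.obs + i * n for i in range(b)]),
                sub=np.concatenate([p.sub + i * S for i in range(b)]),
                dose=np.tile(p.dose, b),
                dt=np.tile(p.dt, b),
                tau=np.tile(p.tau, b),
                agg=sp.block_diag([p.agg] * b, format="csr"),
            )
        tiled = Design(
            subject_ids=np.tile(self.subject_ids, b),
            obs_subject=np.concatenate([self.obs_subject + i * S for i in range(b)]),
            obs_dvid=np.tile(self.obs_dvid, b),
            obs_time=np.tile(self.obs_time, b),
            obs_tad=np.tile(self.obs_tad, b),
            y=np.tile(self.y, b),
            subject_slices=slices,
            pairs=pairs,
            cov={k: np.tile(v, b) for k, v in self.cov.items()},
            n_dropped_structural_zero=self.n_dropped_structural_zero,
            skipped_subjects=list(self.skipped_subjects),
        )
        tiled.base = self
        tiled.n_blocks = b
        cache[b] = tiled
        return tiled
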