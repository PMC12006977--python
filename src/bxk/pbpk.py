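"""Whole-body amyloid-beta kinetics (PBPK) driven by the blast response.

Species and compartments
------------------------
Brain tissue carries the amyloidogenic pathway: APP is synthesized at
rate ``k_APP(t) = k_APP0 * (1 + x * R_B(t))`` (blast-amplified), cleaved
by BACE1 into C99 (+ sAPPbeta), and C99 by gamma-secretase into Abeta
(+ AICD); a fraction ``f_42`` of the Abeta flux is Abeta42, released
into the brain interstitial fluid (ISF).  A peripheral tissue pathway
synthesizes APP at ``f_per * k_APP0`` (unmodulated by default).

Abeta42 then moves between six compartments — brain ISF, brain
vascular, perivascular (glymphatic) space, central plasma, peripheral
tissue, and lymph — via:

* BBB transporters: LRP1 and P-gP efflux (ISF -> vascular), RAGE
  influx (vascular -> ISF), first-order by default;
* bidirectional BBB fluid exchange ``F_BBB``;
* glymphatic flux ``F_gly`` (ISF -> perivascular -> lymph);
* plasma/tissue flows ``Q`` with lymph drainage ``L`` returning to
  plasma, as in a standard flow-limited PBPK layout.

All inter-compartment terms are built pairwise (an amount flux leaves
one compartment and enters another scaled by the receiving volume), so
the transport subsystem conserves total Abeta42 mass by construction.
Serum concentration is identified with the plasma compartment.
"""

from __future__ import annotations

import numpy as np

from .config import ConfigError, PBPKConfig
from .exposure import InputError

AB42_COMPARTMENTS = ("isf", "vas", "pvs", "pla", "per", "lym")


def app_synthesis_rate(k_app0: float, x: float, r_b: float) -> float:
    """Blast-modulated APP synthesis rate k_APP0 * (1 + x * R_B), pg/mL/h."""
    if r_b < 0:
        raise InputError(f"biological response R_B must be >= 0, got {r_b}")
    return k_app0 * (1.0 + x * r_b)


class PBPKSystem:
    """Linear mass-balance ODE system over the amyloid species.

    The state is a concentration vector (pg/mL) ordered as in
    ``self.species``.  The dynamics are ``dc/dt = A c + b(t)`` where the
    forcing ``b`` carries APP synthesis (time-varying through the blast
    response); with saturable transport enabled the BBB transporter
    terms become Michaelis-type and are applied outside ``A``.
    """

    def __init__(self, config: PBPKConfig) -> None:
        p = config
        if p.q_br < p.l_br:
            raise ConfigError("pbpk.q_br must be >= pbpk.l_br (brain lymph drains from the flow)")
        if p.q_per < p.l_per:
            raise ConfigError("pbpk.q_per must be >= pbpk.l_per")
        self.config = p

        species = ["app_br", "c99_br"]
        species += [f"ab42_{c}" for c in AB42_COMPARTMENTS]
        species += ["app_per", "c99_per"]
        if p.include_ab40:
            species += [f"ab40_{c}" for c in AB42_COMPARTMENTS]
        if p.include_byproducts:
            species += ["sappb_br", "aicd_br", "sbace1_br"]
        self.species = species
        self.index = {name: i for i, name in enumerate(species)}
        self.n = len(species)

        vols = {
            "isf": p.v_isf, "vas": p.v_vas, "pvs": p.v_pvs,
            "pla": p.v_pla, "per": p.v_per, "lym": p.v_lym,
        }
        volumes = np.ones(self.n)
        for name, i in self.index.items():
            if name.startswith(("ab42_", "ab40_")):
                volumes[i] = vols[name.rsplit("_", 1)[1]]
            elif name.endswith("_per"):
                volumes[i] = p.v_per
            else:  # brain tissue species share the ISF volume
                volumes[i] = p.v_isf
        self.volumes = volumes

        self._build_matrix()
        self.k_app0 = self._resolve_k_app0()

    # -- construction -------------------------------------------------

    def _add_flow(self, A: np.ndarray, src: int, dst: int, amount_coeff: float) -> None:
        """Amount flux ``amount_coeff * C_src`` (pg/h) from src to dst."""
        A[src, src] -= amount_coeff / self.volumes[src]
        A[dst, src] += amount_coeff / self.volumes[dst]

    def _transport_block(self, A: np.ndarray, prefix: str, include_transporters: bool) -> None:
        p = self.config
        ix = {c: self.index[f"{prefix}_{c}"] for c in AB42_COMPARTMENTS}
        if include_transporters:
            self._add_flow(A, ix["isf"], ix["vas"], (p.k_lrp1 + p.k_pgp) * p.v_isf)
            self._add_flow(A, ix["vas"], ix["isf"], p.k_rage * p.v_vas)
        self._add_flow(A, ix["isf"], ix["vas"], p.f_bbb)
        self._add_flow(A, ix["vas"], ix["isf"], p.f_bbb)
        self._add_flow(A, ix["isf"], ix["pvs"], p.f_gly)
        self._add_flow(A, ix["pvs"], ix["lym"], p.f_gly)
        self._add_flow(A, ix["pla"], ix["vas"], p.q_br)
        self._add_flow(A, ix["vas"], ix["pla"], p.q_br - p.l_br)
        self._add_flow(A, ix["vas"], ix["lym"], p.l_br)
        self._add_flow(A, ix["pla"], ix["per"], p.q_per)
        self._add_flow(A, ix["per"], ix["pla"], p.q_per - p.l_per)
        self._add_flow(A, ix["per"], ix["lym"], p.l_per)
        self._add_flow(A, ix["lym"], ix["pla"], p.l_br + p.l_per + p.f_gly)
        for c in AB42_COMPARTMENTS:
            A[ix[c], ix[c]] -= getattr(p, f"k_deg_{c}")

    def _build_matrix(self) -> None:
        p = self.config
        A = np.zeros((self.n, self.n))
        ix = self.index
        # amyloidogenic pathway, brain
        A[ix["app_br"], ix["app_br"]] -= p.k_bace1
        A[ix["c99_br"], ix["app_br"]] += p.k_bace1
        A[ix["c99_br"], ix["c99_br"]] -= p.k_gs
        A[ix["ab42_isf"], ix["c99_br"]] += p.f_42 * p.k_gs
        # peripheral pathway (Abeta released into peripheral tissue)
        A[ix["app_per"], ix["app_per"]] -= p.k_bace1
        A[ix["c99_per"], ix["app_per"]] += p.k_bace1
        A[ix["c99_per"], ix["c99_per"]] -= p.k_gs
        A[ix["ab42_per"], ix["c99_per"]] += p.f_42 * p.k_gs
        # Abeta42 transport (transporters linearly unless saturable)
        self._transport_block(A, "ab42", include_transporters=not p.saturable_transport)
        if p.include_ab40:
            A[ix["ab40_isf"], ix["c99_br"]] += (1.0 - p.f_42) * p.k_gs
            A[ix["ab40_per"], ix["c99_per"]] += (1.0 - p.f_42) * p.k_gs
            self._transport_block(A, "ab40", include_transporters=not p.saturable_transport)
        if p.include_byproducts:
            A[ix["sappb_br"], ix["app_br"]] += p.k_bace1
            A[ix["sbace1_br"], ix["app_br"]] += p.k_bace1
            A[ix["aicd_br"], ix["c99_br"]] += p.k_gs
            for s in ("sappb_br", "aicd_br", "sbace1_br"):
                A[ix[s], ix[s]] -= p.k_byproduct_elim
        self.A = A

    def _resolve_k_app0(self) -> float:
        if self.config.k_app0 == "auto":
            plasma_unit = self._steady_state_for(1.0)[self.index["ab42_pla"]]
            if plasma_unit <= 0:
                raise ConfigError(
                    "cannot auto-scale pbpk.k_app0: baseline plasma Abeta42 is zero "
                    "(check synthesis and transport parameters)"
                )
            return self.config.baseline_plasma_pg_ml / plasma_unit
        return float(self.config.k_app0)

    # -- forcing and RHS ----------------------------------------------

    def forcing(self, k_app_brain: float, k_app_peripheral: float | None = None) -> np.ndarray:
        """Forcing vector for instantaneous synthesis rates (pg/mL/h in brain)."""
        p = self.config
        b = np.zeros(self.n)
        b[self.index["app_br"]] = k_app_brain
        if k_app_peripheral is None:
            k_app_peripheral = p.f_per * self.k_app0
        # peripheral synthesis is an amount rate f_per * (k_app0 * V_isf)
        b[self.index["app_per"]] = k_app_peripheral * self.volumes[self.index["app_br"]] / p.v_per
        return b

    def _saturable_extra(self, c: np.ndarray) -> np.ndarray:
        """Michaelis transporter fluxes (only when saturable_transport)."""
        p = self.config
        out = np.zeros(self.n)
        for prefix in ("ab42",) + (("ab40",) if p.include_ab40 else ()):
            i_isf = self.index[f"{prefix}_isf"]
            i_vas = self.index[f"{prefix}_vas"]
            sat_isf = 1.0 / (1.0 + max(c[i_isf], 0.0) / p.km_transport)
            sat_vas = 1.0 / (1.0 + max(c[i_vas], 0.0) / p.km_transport)
            efflux = (p.k_lrp1 + p.k_pgp) * c[i_isf] * sat_isf * p.v_isf
            influx = p.k_rage * c[i_vas] * sat_vas * p.v_vas
            out[i_isf] += (influx - efflux) / p.v_isf
            out[i_vas] += (efflux - influx) / p.v_vas
        return out

    def rhs(self, c: np.ndarray, r_b: float) -> np.ndarray:
        """dc/dt at response level ``r_b`` (the blast-dose coupling point)."""
        p = self.config
        k_brain = app_synthesis_rate(self.k_app0, p.x, r_b)
        k_per = p.f_per * (k_brain if p.modulate_peripheral else self.k_app0)
        dc = self.A @ c + self.forcing(k_brain, k_per)
        if p.saturable_transport:
            dc += self._saturable_extra(c)
        return dc

    # -- steady state --------------------------------------------------

    def _steady_state_for(self, k_app0: float) -> np.ndarray:
        p = self.config
        b = np.zeros(self.n)
        b[self.index["app_br"]] = k_app0
        b[self.index["app_per"]] = p.f_per * k_app0 * self.volumes[self.index["app_br"]] / p.v_per
        for name, i in self.index.items():
            if b[i] > 0 and self.A[i, i] >= 0:
                raise ConfigError(
                    f"compartment {name!r} receives inflow but has no outflow; "
                    "steady state is undefined"
                )
        try:
            c = np.linalg.solve(self.A, -b)
        except np.linalg.LinAlgError as exc:
            raise ConfigError(f"singular PBPK system: {exc}") from exc
        if np.any(c < -1e-9 * max(1.0, np.abs(c).max())):
            raise ConfigError("PBPK steady state has negative concentrations")
        return np.clip(c, 0.0, None)

    def steady_state(self) -> np.ndarray:
        """Baseline state (R_B = 0); residual ||A c + b|| ~ 0 by direct solve."""
        base = self._steady_state_for(self.k_app0)
        if self.config.saturable_transport:
            from scipy.optimize import fsolve

            base, info, ier, msg = fsolve(
                lambda c: self.rhs(c, 0.0), base, full_output=True, xtol=1e-12
            )
            if ier != 1:
                raise ConfigError(f"saturable steady state did not converge: {msg}")
            base = np.clip(base, 0.0, None)
        return base

    @property
    def plasma_index(self) -> int:
        return self.index["ab42_pla"]
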