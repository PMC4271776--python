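"""Closed-form kinetics of a symmetric carrier-mediated amino acid transporter.

A membrane carrier X binds a single substrate molecule on either membrane
face, translocates as the loaded complex (AX or BX) with equal forward and
backward rates, and may also translocate unloaded with relative mobility
``h``.  The single parameter ``h`` spans the mechanistic continuum from an
obligatory exchanger (antiport, ``h = 0``: no flux without counter-substrate
on the trans side) to facilitated diffusion (uniport, ``h > 0``: net
transport down the gradient to diffusive equilibrium).

Radiolabelled tracer A and unlabelled substrate B are kinetically identical;
only their labels differ.  With equal dissociation constants ``K`` on both
faces and a maximal rate ``V`` (flux already scaled by vesicle volume, so in
concentration per time), the tracer influx into the vesicle is

    d[A]_in/dt = 2V ( [A]_out ([B]_in + Kh) - [A]_in ([B]_out + Kh) ) / D

    D = 2 Tot_out Tot_in + K (h+1) (Tot_out + Tot_in) + 2 h K**2

where ``Tot = [A] + [B]`` on each face.  Under zero-trans initial conditions
([A]_in = 0) this reduces exactly to a Michaelis-Menten law in the total
external concentration, with apparent parameters

    Vapp = 2V ([B]_in0 + Kh) / (2 [B]_in0 + K (h+1))
    Kapp = (K (h+1) [B]_in0 + 2 h K**2) / (2 [B]_in0 + K (h+1))

that depend on the mechanism (``h``) and on any unlabelled substrate present
inside the vesicle — so a measured (Vapp, Kapp) pair maps to a different
intrinsic (V, K) for every assumed (h, [B]_in0); :func:`invert_apparent`
performs that mapping in closed form.

Units are fixed internally: concentrations in µmol l⁻¹, rates in
µmol l⁻¹ min⁻¹, time in minutes.  Experimental seconds are converted at the
I/O boundary (:mod:`carrierflux.interface_io`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

__all__ = [
    "TransporterParams",
    "CompartmentState",
    "ApparentMM",
    "InversionContext",
    "ObligatoryExchangeError",
    "tracer_influx",
    "unlabelled_influx",
    "total_influx",
    "flux_denominator",
    "initial_uptake_rate",
    "apparent_params",
    "invert_apparent",
    "equilibrium_state",
]


class ObligatoryExchangeError(ValueError):
    """Raised for the unphysical configuration h = 0 with no internal substrate.

    An obligatory exchanger with an empty trans compartment cannot transport,
    so apparent Michaelis-Menten parameters are undefined there.
    """


def _check_nonneg(name: str, value: float) -> float:
    if not math.isfinite(value):
        raise ValueError(f"{name} must be finite, got {value!r}")
    if value < 0:
        raise ValueError(f"{name} must be >= 0, got {value!r}")
    return float(value)


@dataclass(frozen=True)
class TransporterParams:
    """Intrinsic kinetic constants of the carrier cycle.

    Parameters
    ----------
    V : float
        Maximal transport rate, µmol l⁻¹ min⁻¹ (flux divided by vesicle
        volume).
    K : float
        Substrate-carrier dissociation constant, µmol l⁻¹; equal on both
        membrane faces by the symmetry assumption.
    h : float
        Relative mobility of the unloaded carrier (dimensionless).
        ``h = 0`` is an obligatory exchanger, ``h > 0`` facilitative
        transport, ``h = 1`` equal loaded/unloaded mobility.
    """

    V: float
    K: float
    h: float

    def __post_init__(self) -> None:
        _check_nonneg("V", self.V)
        if not (math.isfinite(self.K) and self.K > 0):
            raise ValueError(f"K must be > 0, got {self.K!r}")
        _check_nonneg("h", self.h)


@dataclass(frozen=True)
class CompartmentState:
    """Tracer and unlabelled concentrations on both membrane faces (µmol l⁻¹).

    ``_out`` is the extravesicular face (side I), ``_in`` the intravesicular
    face (side II).
    """

    A_out: float
    B_out: float
    A_in: float
    B_in: float

    def __post_init__(self) -> None:
        for name in ("A_out", "B_out", "A_in", "B_in"):
            _check_nonneg(name, getattr(self, name))

    @property
    def tot_out(self) -> float:
        """Total external substrate, tracer plus unlabelled."""
        return self.A_out + self.B_out

    @property
    def tot_in(self) -> float:
        """Total internal substrate, tracer plus unlabelled."""
        return self.A_in + self.B_in


@dataclass(frozen=True)
class ApparentMM:
    """Apparent Michaelis-Menten pair for a zero-trans initial-rate experiment.

    ``Vapp`` in µmol l⁻¹ min⁻¹, ``Kapp`` in µmol l⁻¹; both are functions of
    the intrinsic (V, K, h) and of the internal unlabelled concentration.
    """

    Vapp: float
    Kapp: float

    def __post_init__(self) -> None:
        _check_nonneg("Vapp", self.Vapp)
        if not (math.isfinite(self.Kapp) and self.Kapp > 0):
            raise ValueError(f"Kapp must be > 0, got {self.Kapp!r}")


@dataclass(frozen=True)
class InversionContext:
    """Mechanistic assumptions under which apparent parameters are inverted.

    ``h`` is the assumed unloaded-carrier mobility and ``B_in0`` the assumed
    initial internal unlabelled concentration (µmol l⁻¹).  The pair
    (h = 0, B_in0 = 0) is rejected: an obligatory exchanger with nothing
    inside shows no uptake, so no intrinsic parameters can reproduce a
    non-trivial apparent pair.
    """

    h: float
    B_in0: float

    def __post_init__(self) -> None:
        _check_nonneg("h", self.h)
        _check_nonneg("B_in0", self.B_in0)
        if self.h == 0 and self.B_in0 == 0:
            raise ObligatoryExchangeError(
                "obligatory exchanger (h=0) with no internal substrate "
                "(B_in0=0) admits no uptake"
            )


# -- raw flux arithmetic (floats in, floats out; used by the integrator) ----

def _denominator(A_out: float, B_out: float, A_in: float, B_in: float,
                 V: float, K: float, h: float) -> float:
    tot_out = A_out + B_out
    tot_in = A_in + B_in
    return 2.0 * tot_out * tot_in + K * (h + 1.0) * (tot_out + tot_in) \
        + 2.0 * h * K * K


def _tracer_flux(A_out: float, B_out: float, A_in: float, B_in: float,
                 V: float, K: float, h: float) -> float:
    num = 2.0 * V * (A_out * (B_in + K * h) - A_in * (B_out + K * h))
    den = _denominator(A_out, B_out, A_in, B_in, V, K, h)
    if den == 0.0:
        # h = 0 and every concentration 0: no substrate anywhere, no flux.
        return 0.0
    return num / den


def _unlabelled_flux(A_out: float, B_out: float, A_in: float, B_in: float,
                     V: float, K: float, h: float) -> float:
    # A and B have identical kinetics; swap the labels in the numerator.
    num = 2.0 * V * (B_out * (A_in + K * h) - B_in * (A_out + K * h))
    den = _denominator(A_out, B_out, A_in, B_in, V, K, h)
    if den == 0.0:
        return 0.0
    return num / den


# -- public, validated surface ----------------------------------------------

def flux_denominator(state: CompartmentState, params: TransporterParams) -> float:
    """Common denominator D of the carrier flux law."""
    return _denominator(state.A_out, state.B_out, state.A_in, state.B_in,
                        params.V, params.K, params.h)


def tracer_influx(state: CompartmentState, params: TransporterParams) -> float:
    """Net inward tracer flux d[A]_in/dt, µmol l⁻¹ min⁻¹.

    Positive for net inward tracer movement.  The degenerate 0/0 case
    (h = 0 with all four concentrations zero) is defined as 0, the physically
    forced value.
    """
    return _tracer_flux(state.A_out, state.B_out, state.A_in, state.B_in,
                        params.V, params.K, params.h)


def unlabelled_influx(state: CompartmentState, params: TransporterParams) -> float:
    """Net inward unlabelled-substrate flux d[B]_in/dt, µmol l⁻¹ min⁻¹.

    Tracer and unlabelled substrate are kinetically identical, so this is the
    tracer flux law with the A and B labels exchanged.  For h = 0 it equals
    minus the tracer influx on every state (strict 1:1 exchange).
    """
    return _unlabelled_flux(state.A_out, state.B_out, state.A_in, state.B_in,
                            params.V, params.K, params.h)


def total_influx(state: CompartmentState, params: TransporterParams) -> float:
    """Net inward total-substrate flux, d(A_in+B_in)/dt.

    Equals 2 V K h (Tot_out − Tot_in) / D; identically zero for an
    obligatory exchanger.
    """
    return tracer_influx(state, params) + unlabelled_influx(state, params)


def initial_uptake_rate(A_out0: float, B_out0: float, B_in0: float,
                        params: TransporterParams) -> float:
    """Zero-trans initial tracer uptake rate, µmol l⁻¹ min⁻¹.

    Evaluates the full flux law on the state (A_out0, B_out0, A_in=0, B_in0).
    Algebraically identical to the Michaelis-Menten reduction
    ``Vapp A_out0 / (Tot_out0 + Kapp)`` with (Vapp, Kapp) from
    :func:`apparent_params`; the equality is property-tested.
    """
    state = CompartmentState(A_out=A_out0, B_out=B_out0, A_in=0.0, B_in=B_in0)
    return tracer_influx(state, params)


def apparent_params(params: TransporterParams, B_in0: float) -> ApparentMM:
    """Apparent Michaelis-Menten parameters of a zero-trans experiment.

    Parameters
    ----------
    params : TransporterParams
        Intrinsic carrier constants.
    B_in0 : float
        Initial internal unlabelled concentration, µmol l⁻¹.

    Raises
    ------
    ObligatoryExchangeError
        If ``params.h == 0`` and ``B_in0 == 0`` (no uptake possible).

    Notes
    -----
    For ``h = 1`` the result is (V, K) regardless of ``B_in0``: when loaded
    and unloaded carrier move at the same rate, internal substrate cannot
    change the return rate of the carrier and the apparent parameters equal
    the intrinsic ones.
    """
    _check_nonneg("B_in0", B_in0)
    V, K, h = params.V, params.K, params.h
    if h == 0 and B_in0 == 0:
        raise ObligatoryExchangeError(
            "obligatory exchanger with no internal substrate: apparent "
            "parameters undefined (no uptake)"
        )
    den = 2.0 * B_in0 + K * (h + 1.0)
    Vapp = 2.0 * V * (B_in0 + K * h) / den
    Kapp = (K * (h + 1.0) * B_in0 + 2.0 * h * K * K) / den
    return ApparentMM(Vapp=Vapp, Kapp=Kapp)


def invert_apparent(apparent: ApparentMM, ctx: InversionContext) -> TransporterParams:
    """Intrinsic (V, K) reproducing a measured apparent pair under ``ctx``.

    The Kapp relation rearranges to a quadratic in K,

        2 h K² + (h+1) (B_in0 − Kapp) K − 2 B_in0 Kapp = 0,

    linear for h = 0 and with a unique positive root for h > 0 (the constant
    term is non-positive).  V then follows from the Vapp relation:
    ``V = Vapp (2 B_in0 + K (h+1)) / (2 (B_in0 + K h))``.

    Raises
    ------
    ObligatoryExchangeError
        For ctx = (h=0, B_in0=0), where no uptake is possible.
    ValueError
        If no positive K root exists (h = 0 with B_in0 <= Kapp: an
        obligatory exchanger cannot produce an apparent Kapp at or above the
        internal pool concentration).
    """
    Vapp, Kapp = apparent.Vapp, apparent.Kapp
    h, B = ctx.h, ctx.B_in0
    if h == 0:
        if B <= Kapp:
            raise ValueError(
                f"no positive K root: h=0 requires B_in0 > Kapp "
                f"(got B_in0={B}, Kapp={Kapp})"
            )
        K = 2.0 * B * Kapp / (B - Kapp)
    elif B == 0:
        K = (h + 1.0) * Kapp / (2.0 * h)
    else:
        a = 2.0 * h
        b = (h + 1.0) * (B - Kapp)
        c = -2.0 * B * Kapp
        disc = b * b - 4.0 * a * c  # c < 0 here, so disc > b**2 >= 0
        if b >= 0.0:
            # cancellation-stable form of the positive root for small h
            K = 2.0 * c / (-b - math.sqrt(disc))
        else:
            K = (-b + math.sqrt(disc)) / (2.0 * a)
    V = Vapp * (2.0 * B + K * (h + 1.0)) / (2.0 * (B + K * h))
    return TransporterParams(V=V, K=K, h=h)


def equilibrium_state(initial: CompartmentState, params: TransporterParams,
                      constant_bath: bool = True) -> CompartmentState:
    """Long-time state of the vesicle under a constant external bath.

    For a facilitative carrier (h > 0) both species relax to diffusive
    equilibrium with the bath (A_in = A_out, B_in = B_out).  An obligatory
    exchanger (h = 0) conserves the internal total, and at equilibrium the
    internal tracer fraction matches the external one:
    ``A_in = Tot_in(0) · A_out / Tot_out``.  With tracer alone outside this
    means the whole internal pool ends up labelled — the internal tracer
    equilibrates above the bath concentration whenever Tot_in(0) > A_out.

    If h = 0 and the bath is empty the flux numerator vanishes identically
    and the initial state is returned unchanged.
    """
    if not constant_bath:
        raise NotImplementedError(
            "only the constant-bath (large extravesicular volume) regime "
            "is modelled"
        )
    if params.h > 0:
        return replace(initial, A_in=initial.A_out, B_in=initial.B_out)
    tot_in = initial.tot_in
    tot_out = initial.tot_out
    if tot_out == 0.0:
        return initial
    return replace(initial,
                   A_in=tot_in * initial.A_out / tot_out,
                   B_in=tot_in * initial.B_out / tot_out)
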