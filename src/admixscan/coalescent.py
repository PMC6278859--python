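"""Neutral coalescent null distributions from an ms-dialect demography.

The demographic model is specified with the classic ms command syntax
(times in units of 4N0 generations, sizes relative to N0, migration in
4N0·m units). Supported flags: -t -r -I -n -g -ma -es -ej -en -eM, with
``tbs`` marking per-replicate theta/rho values. Simulation itself runs on
msprime (Hudson structured coalescent with recombination, infinite-sites
binary mutations), after an exact unit conversion; ms event semantics are
preserved, including -ej zeroing backward migration out of the joined deme
and a later -eM resetting every off-diagonal rate to x/(npop-1).
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field

import numpy as np

#: N0 used for any absolute-unit conversion (reporting only)
DEFAULT_N0 = 7310.0

#: the four-population null demography used for the Canary Islander
#: selection tests: African(1)/European(2)/Asian(3) reference model plus an
#: isolated Canarian deme (4) of aboriginal size Ne≈497 that receives a 90%
#: European admixture pulse ~15 generations ago; 28 sampled haplotypes.
CANARIAN_NULL_COMMAND = (
    "./msHOT 28 5000 -t tbs -r tbs 10000 "
    "-I 4 0 0 0 28 "
    "-n 1 1.68202 -n 2 3.73683 -n 3 7.29205 -n 4 3.73683 "
    "-g 2 116.010723 -g 3 160.246047 "
    "-ma x 0.881098 0.561966 0 0.881098 x 2.79746 10 "
    "0.561966 2.79746 x 0 0 1 0 x "
    "-es 0.0005 4 0.1 -ej 0.0005 5 2 -en 0.0005 4 0.068 "
    "-ej 0.0135 4 1 -ej 0.028985 3 2 -en 0.028985 2 0.287184 "
    "-eM 0.028985 28 -ej 0.197963 2 1 -en 0.303501 1 1"
)


class MsParseError(ValueError):
    pass


@dataclass
class Event:
    time: float
    kind: str          # es | ej | en | eM
    params: tuple


@dataclass
class LocusParams:
    theta: float
    rho: float = 0.0
    length_bp: int = 10_000

    def __post_init__(self):
        if not self.theta > 0:
            raise ValueError("theta must be positive")
        if self.rho < 0:
            raise ValueError("rho must be non-negative")


@dataclass
class DemographicModel:
    nsam: int
    nreps: int
    theta: float | str = "tbs"          # float or "tbs"
    rho: float | str = 0.0
    length_bp: int = 1
    npop: int = 1
    sample_config: list = field(default_factory=list)
    sizes: list = field(default_factory=list)      # relative to N0
    growth: list = field(default_factory=list)     # ms alpha units
    migration: np.ndarray | None = None            # 4N0 m units
    events: list = field(default_factory=list)

    def __post_init__(self):
        if not self.sample_config:
            self.sample_config = [self.nsam]
        if sum(self.sample_config) != self.nsam:
            raise ValueError("sample sizes must sum to nsam")
        if not self.sizes:
            self.sizes = [1.0] * self.npop
        if not self.growth:
            self.growth = [0.0] * self.npop
        if self.migration is None:
            self.migration = np.zeros((self.npop, self.npop))
        times = [e.time for e in self.events]
        if any(t < 0 for t in times):
            raise ValueError("event times must be >= 0")
        if times != sorted(times):
            raise ValueError("events must be time-ordered")

    @property
    def n_derived_pops(self) -> int:
        return sum(1 for e in self.events if e.kind == "es")

    @property
    def total_pops(self) -> int:
        return self.npop + self.n_derived_pops

    @property
    def has_tbs(self) -> bool:
        return self.theta == "tbs" or self.rho == "tbs"

    def model_hash(self) -> str:
        payload = json.dumps({
            "nsam": self.nsam, "npop": self.npop,
            "samples": self.sample_config, "sizes": self.sizes,
            "growth": self.growth,
            "mig": None if self.migration is None else self.migration.tolist(),
            "events": [(e.time, e.kind, e.params) for e in self.events],
            "theta": self.theta, "rho": self.rho, "L": self.length_bp,
        }, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def parse_ms_command(cmdline: str) -> DemographicModel:
    """Parse an ms/msHOT command string into a DemographicModel."""
    toks = cmdline.replace("*", " ").split()
    # drop program name and shell redirections
    if toks and not _is_number(toks[0]):
        toks = toks[1:]
    for redir in ("<", ">"):
        if redir in toks:
            toks = toks[:toks.index(redir)]
    toks = [t for t in toks if t not in ("<", ">")]
    if len(toks) < 2:
        raise MsParseError("command too short: need nsam and nreps")
    nsam, nreps = int(toks[0]), int(toks[1])
    i = 2
    theta: float | str = 0.0
    rho: float | str = 0.0
    length_bp = 1
    npop, sample_config = 1, [nsam]
    sizes: dict[int, float] = {}
    growth: dict[int, float] = {}
    migration = None
    events: list[Event] = []

    def number(tok):
        return tok if tok == "tbs" else float(tok)

    while i < len(toks):
        flag = toks[i]
        try:
            if flag == "-t":
                theta = number(toks[i + 1]); i += 2
            elif flag == "-r":
                rho = number(toks[i + 1]); length_bp = int(toks[i + 2]); i += 3
            elif flag == "-I":
                npop = int(toks[i + 1])
                sample_config = [int(x) for x in toks[i + 2:i + 2 + npop]]
                i += 2 + npop
                # optional trailing symmetric migration rate
                if i < len(toks) and _is_number(toks[i]):
                    m = float(toks[i]); i += 1
                    migration = np.full((npop, npop), m / (npop - 1))
                    np.fill_diagonal(migration, 0.0)
            elif flag == "-n":
                sizes[int(toks[i + 1]) - 1] = float(toks[i + 2]); i += 3
            elif flag == "-g":
                growth[int(toks[i + 1]) - 1] = float(toks[i + 2]); i += 3
            elif flag == "-ma":
                vals = toks[i + 1:i + 1 + npop * npop]
                migration = np.array(
                    [0.0 if v in ("x", "X", "-") else float(v) for v in vals]
                ).reshape(npop, npop)
                np.fill_diagonal(migration, 0.0)
                i += 1 + npop * npop
            elif flag == "-es":
                events.append(Event(float(toks[i + 1]), "es",
                                    (int(toks[i + 2]) - 1, float(toks[i + 3]))))
                i += 4
            elif flag == "-ej":
                events.append(Event(float(toks[i + 1]), "ej",
                                    (int(toks[i + 2]) - 1, int(toks[i + 3]) - 1)))
                i += 4
            elif flag == "-en":
                events.append(Event(float(toks[i + 1]), "en",
                                    (int(toks[i + 2]) - 1, float(toks[i + 3]))))
                i += 4
            elif flag == "-eM":
                events.append(Event(float(toks[i + 1]), "eM",
                                    (float(toks[i + 2]),)))
                i += 3
            else:
                raise MsParseError(f"unsupported flag: {flag}")
        except (IndexError, ValueError) as exc:
            if isinstance(exc, MsParseError):
                raise
            raise MsParseError(f"malformed arguments for {flag}") from exc

    order = sorted(range(len(events)), key=lambda j: events[j].time)
    events = [events[j] for j in order]  # stable: command order at equal times
    model = DemographicModel(
        nsam=nsam, nreps=nreps, theta=theta, rho=rho, length_bp=length_bp,
        npop=npop, sample_config=sample_config,
        sizes=[sizes.get(k, 1.0) for k in range(npop)],
        growth=[growth.get(k, 0.0) for k in range(npop)],
        migration=migration, events=events,
    )
    return model


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def serialize_ms_command(model: DemographicModel) -> str:
    """Canonical ms command string (inverse of parse up to normalization)."""
    parts = [f"ms {model.nsam} {model.nreps}"]
    if model.theta != 0.0:
        parts.append(f"-t {model.theta}")
    if model.rho != 0.0 or model.length_bp > 1:
        parts.append(f"-r {model.rho} {model.length_bp}")
    if model.npop > 1:
        parts.append("-I " + str(model.npop) + " "
                     + " ".join(str(x) for x in model.sample_config))
        for k, x in enumerate(model.sizes):
            if x != 1.0:
                parts.append(f"-n {k + 1} {_fmt(x)}")
        for k, a in enumerate(model.growth):
            if a != 0.0:
                parts.append(f"-g {k + 1} {_fmt(a)}")
        if model.migration is not None and np.any(model.migration != 0):
            vals = []
            for a in range(model.npop):
                for b in range(model.npop):
                    vals.append("x" if a == b else _fmt(model.migration[a, b]))
            parts.append("-ma " + " ".join(vals))
    for e in model.events:
        if e.kind == "es":
            parts.append(f"-es {_fmt(e.time)} {e.params[0] + 1} {_fmt(e.params[1])}")
        elif e.kind == "ej":
            parts.append(f"-ej {_fmt(e.time)} {e.params[0] + 1} {e.params[1] + 1}")
        elif e.kind == "en":
            parts.append(f"-en {_fmt(e.time)} {e.params[0] + 1} {_fmt(e.params[1])}")
        elif e.kind == "eM":
            parts.append(f"-eM {_fmt(e.time)} {_fmt(e.params[0])}")
    return " ".join(parts)


def _fmt(x: float) -> str:
    return f"{x:.12g}"


# ---------------------------------------------------------------------------
# msprime backend
# ---------------------------------------------------------------------------

def to_demography(model: DemographicModel, N0: float = DEFAULT_N0):
    """Convert ms units to an msprime.Demography (generations, diploid N)."""
    import msprime

    dem = msprime.Demography()
    for k in range(model.npop):
        dem.add_population(
            name=f"pop{k + 1}",
            initial_size=model.sizes[k] * N0,
            growth_rate=model.growth[k] / (4.0 * N0),
        )
    n_es = 0
    for e in model.events:
        if e.kind == "es":
            n_es += 1
            dem.add_population(name=f"pop{model.npop + n_es}",
                               initial_size=N0, growth_rate=0.0)
    if model.migration is not None:
        for a in range(model.npop):
            for b in range(model.npop):
                if a != b and model.migration[a, b] != 0.0:
                    dem.set_migration_rate(source=f"pop{a + 1}",
                                           dest=f"pop{b + 1}",
                                           rate=model.migration[a, b] / (4.0 * N0))
    npop_now = model.npop
    all_names = [f"pop{k + 1}" for k in range(model.total_pops)]
    for e in model.events:
        t = e.time * 4.0 * N0
        if e.kind == "es":
            npop_now += 1
            new = f"pop{npop_now}"
            src = f"pop{e.params[0] + 1}"
            dem.add_mass_migration(time=t, source=src, dest=new,
                                   proportion=1.0 - e.params[1])
        elif e.kind == "ej":
            src = f"pop{e.params[0] + 1}"
            dst = f"pop{e.params[1] + 1}"
            dem.add_mass_migration(time=t, source=src, dest=dst, proportion=1.0)
            for other in all_names[:npop_now]:
                if other != src:
                    dem.add_migration_rate_change(time=t, rate=0.0,
                                                  source=src, dest=other)
        elif e.kind == "en":
            dem.add_population_parameters_change(
                time=t, population=f"pop{e.params[0] + 1}",
                initial_size=e.params[1] * N0, growth_rate=0.0)
        elif e.kind == "eM":
            rate = e.params[0] / (npop_now - 1) / (4.0 * N0) if npop_now > 1 else 0.0
            dem.add_migration_rate_change(time=t, rate=rate)
    dem.sort_events()
    return dem


def simulate_locus(model: DemographicModel, lp: LocusParams | None = None,
                   seed: int = 1, N0: float = DEFAULT_N0,
                   extra_samples: dict[int, int] | None = None
                   ) -> tuple[np.ndarray, np.ndarray]:
    """Simulate one locus; returns (haplotypes x sites 0/1 matrix,
    positions scaled to (0, 1)).

    ``lp`` resolves any ``tbs`` slots; ``extra_samples`` maps 1-based
    population number -> additional haplotypes (appended after the primary
    sample, e.g. reference panels for PBS nulls).
    """
    import msprime

    if lp is None:
        if model.has_tbs:
            raise ValueError("model has unresolved tbs parameters; "
                             "supply LocusParams")
        lp = LocusParams(theta=float(model.theta), rho=float(model.rho),
                         length_bp=model.length_bp)
    L = float(lp.length_bp)
    mu = lp.theta / (4.0 * N0 * L)
    rr = lp.rho / (4.0 * N0 * L)

    dem = to_demography(model, N0)
    samples = []
    for k, nk in enumerate(model.sample_config):
        if nk > 0:
            samples.append(msprime.SampleSet(nk, population=f"pop{k + 1}",
                                             ploidy=1))
    for pop, nk in (extra_samples or {}).items():
        samples.append(msprime.SampleSet(nk, population=f"pop{pop}", ploidy=1))

    rng = np.random.default_rng(seed)
    s1, s2 = rng.integers(1, 2**31 - 1, size=2)
    ts = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=L,
        recombination_rate=rr, ploidy=2, random_seed=int(s1))
    mts = msprime.sim_mutations(
        ts, rate=mu, model=msprime.BinaryMutationModel(),
        discrete_genome=False, random_seed=int(s2))
    haps = mts.genotype_matrix().T.astype(np.int8)
    # binary model can back-mutate on a site; fold to presence of derived
    haps = (haps > 0).astype(np.int8)
    positions = np.array([s.position for s in mts.sites()]) / L
    return haps, positions


def simulate_replicates(model: DemographicModel, lp: LocusParams,
                        nreps: int, seed: int = 1, N0: float = DEFAULT_N0):
    """Generator of (haplotype matrix, positions) replicates at fixed locus
    parameters; builds the demography once (much faster than repeated
    single-locus calls)."""
    import msprime

    L = float(lp.length_bp)
    mu = lp.theta / (4.0 * N0 * L)
    rr = lp.rho / (4.0 * N0 * L)
    dem = to_demography(model, N0)
    samples = [msprime.SampleSet(nk, population=f"pop{k + 1}", ploidy=1)
               for k, nk in enumerate(model.sample_config) if nk > 0]
    rng = np.random.default_rng(seed)
    s1 = int(rng.integers(1, 2**31 - 1))
    reps = msprime.sim_ancestry(
        samples=samples, demography=dem, sequence_length=L,
        recombination_rate=rr, ploidy=2, random_seed=s1,
        num_replicates=nreps)
    for ts in reps:
        s2 = int(rng.integers(1, 2**31 - 1))
        mts = msprime.sim_mutations(
            ts, rate=mu, model=msprime.BinaryMutationModel(),
            discrete_genome=False, random_seed=s2)
        haps = (mts.genotype_matrix().T > 0).astype(np.int8)
        positions = np.array([s.position for s in mts.sites()]) / L
        yield haps, positions


# ---------------------------------------------------------------------------
# Sample statistics (Hudson sample_stats analogues)
# ---------------------------------------------------------------------------

def tajima_constants(n: int) -> dict[str, float]:
    """Tajima (1989) normalization constants for n sequences."""
    if n < 2:
        raise ValueError("need >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i**2 for i in range(1, n))
    b1 = (n + 1.0) / (3.0 * (n - 1.0))
    b2 = 2.0 * (n * n + n + 3.0) / (9.0 * n * (n - 1.0))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2.0) / (a1 * n) + a2 / (a1 * a1)
    e1 = c1 / a1
    e2 = c2 / (a1 * a1 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2,
            "c1": c1, "c2": c2, "e1": e1, "e2": e2}


def tajimas_d(S: int, pi: float, n: int) -> float:
    """Tajima's D from segregating sites and mean pairwise diversity;
    NaN when S == 0."""
    if S == 0:
        return float("nan")
    k = tajima_constants(n)
    var = k["e1"] * S + k["e2"] * S * (S - 1)
    return (pi - S / k["a1"]) / math.sqrt(var)


def sample_stats(haps: np.ndarray) -> tuple[int, float, float]:
    """(S, pi, D) for a haplotype 0/1 matrix (rows = haplotypes)."""
    haps = np.asarray(haps)
    n, _ = haps.shape
    if n < 2:
        raise ValueError("need >= 2 haplotypes")
    c = haps.sum(axis=0)
    seg = (c > 0) & (c < n)
    S = int(seg.sum())
    pi = float((2.0 * c[seg] * (n - c[seg])).sum() / (n * (n - 1.0)))
    return S, pi, tajimas_d(S, pi, n)


def draw_locus_params(theta_hat: float, rho_hat: float,
                      rng: np.random.Generator,
                      length_bp: int = 10_000) -> LocusParams:
    """Per-replicate (theta, rho) with Normal(mean, variance=mean) noise,
    truncated to positive values by resampling."""
    if not theta_hat > 0:
        raise ValueError("theta_hat must be positive")
    theta = 0.0
    while theta <= 0.0:
        theta = rng.normal(theta_hat, math.sqrt(theta_hat))
    if rho_hat > 0:
        rho = -1.0
        while rho <= 0.0:
            rho = rng.normal(rho_hat, math.sqrt(rho_hat))
    else:
        rho = 0.0
    return LocusParams(theta=theta, rho=rho, length_bp=length_bp)


# ---------------------------------------------------------------------------
# Null ensembles and empirical p-values
# ---------------------------------------------------------------------------

@dataclass
class NullEnsemble:
    """Sorted simulated null values per statistic."""
    values: dict[str, np.ndarray]
    N: int
    model_hash: str = ""
    seed: int | None = None

    def __post_init__(self):
        self.values = {k: np.sort(np.asarray(v, float))
                       for k, v in self.values.items()}
        for k, v in self.values.items():
            if len(v) != self.N:
                raise ValueError(f"ensemble {k} has {len(v)} != N={self.N}")

    def save(self, path) -> None:
        payload = {"N": self.N, "model_hash": self.model_hash,
                   "seed": self.seed,
                   "values": {k: v.tolist() for k, v in self.values.items()}}
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def load(cls, path) -> "NullEnsemble":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(values={k: np.asarray(v) for k, v in payload["values"].items()},
                   N=payload["N"], model_hash=payload["model_hash"],
                   seed=payload["seed"])


@dataclass
class EmpiricalP:
    p: float
    floored: bool  # True means "observed beyond all nulls": report p < 1/N

    def __str__(self) -> str:
        return f"< {self.p:.1e}" if self.floored else f"{self.p:.4g}"


def empirical_p(observed: float, null_values: np.ndarray,
                tail: str = "lower") -> EmpiricalP:
    """Tail proportion of the null at or beyond the observed value;
    zero counts are floored at 1/N and flagged."""
    null_values = np.asarray(null_values, float)
    N = len(null_values)
    if N == 0:
        raise ValueError("empty null ensemble")
    if tail == "lower":
        count = int(np.searchsorted(np.sort(null_values), observed, side="right"))
    elif tail == "upper":
        count = N - int(np.searchsorted(np.sort(null_values), observed, side="left"))
    else:
        raise ValueError("tail must be 'lower' or 'upper'")
    if count == 0:
        return EmpiricalP(1.0 / N, True)
    return EmpiricalP(count / N, False)


def simulate_null_ensemble(model: DemographicModel, theta_hat: float,
                           rho_hat: float, nreps: int | None = None,
                           seed: int = 1, N0: float = DEFAULT_N0,
                           length_bp: int = 10_000,
                           pbs_samples: tuple[int, int] | None = None,
                           pbs_pops: tuple[int, int] | None = None
                           ) -> NullEnsemble:
    """Build the neutral null for Tajima's D (and optionally PBS).

    Each replicate draws (theta, rho) from the randomized locus parameters,
    simulates the demography and computes D on the primary sample. When
    ``pbs_pops=(B, C)`` (1-based population numbers) is given, additional
    haplotypes (``pbs_samples``, default (28, 28)) are sampled from those
    demes and the PBS of the primary population is recorded.
    """
    from .selection import hudson_fst_counts, pbs as pbs_stat

    nreps = nreps or model.nreps
    rng = np.random.default_rng(seed)
    n_primary = sum(model.sample_config)
    extra = None
    if pbs_pops is not None:
        nb, nc = pbs_samples or (28, 28)
        extra = {pbs_pops[0]: nb, pbs_pops[1]: nc}
    d_vals = np.empty(nreps)
    pbs_vals = np.empty(nreps) if pbs_pops is not None else None
    for r in range(nreps):
        lp = draw_locus_params(theta_hat, rho_hat, rng, length_bp=length_bp)
        rep_seed = int(rng.integers(1, 2**31 - 1))
        haps, _ = simulate_locus(model, lp, seed=rep_seed, N0=N0,
                                 extra_samples=extra)
        A = haps[:n_primary]
        _, _, d = sample_stats(A) if A.shape[1] else (0, 0.0, float("nan"))
        d_vals[r] = d
        if pbs_vals is not None:
            nb, nc = pbs_samples or (28, 28)
            B = haps[n_primary:n_primary + nb]
            C = haps[n_primary + nb:n_primary + nb + nc]
            fab = hudson_fst_counts(A.sum(0), np.full(A.shape[1], A.shape[0]),
                                    B.sum(0), np.full(B.shape[1], B.shape[0]))
            fac = hudson_fst_counts(A.sum(0), np.full(A.shape[1], A.shape[0]),
                                    C.sum(0), np.full(C.shape[1], C.shape[0]))
            fbc = hudson_fst_counts(B.sum(0), np.full(B.shape[1], B.shape[0]),
                                    C.sum(0), np.full(C.shape[1], C.shape[0]))
            pbs_vals[r] = pbs_stat(fab, fac, fbc)
    # monomorphic replicates carry no D; represent them at 0 (neutral center)
    d_vals = np.where(np.isnan(d_vals), 0.0, d_vals)
    values = {"D": d_vals}
    if pbs_vals is not None:
        values["PBS"] = np.where(np.isnan(pbs_vals), 0.0, pbs_vals)
    return NullEnsemble(values=values, N=nreps,
                        model_hash=model.model_hash(), seed=seed)
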