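"""Synthetic barcode-library generator with full ground-truth bookkeeping.

The generator emulates the statistical structure a plastid barcode
library confronts, without simulating genealogies: a multi-family /
multi-genus taxonomy; one plastid haplotype pool per species; *haplotype
sharing*, where a species adopts its genus' shared pool haplotype and so
becomes sequence-identical to any congener that did the same;
*introgression / chloroplast capture*, where a donor species' haplotype
overwrites the plastid of chosen recipient individuals (the classic
Poa glauca -> P. hartzii situation); infraspecific taxa; and per-locus
sequence-recovery failure whose probability is logistic in tissue source
and herbarium-specimen age.

Every random draw flows through per-entity generators derived from
``(seed, stream-tag, entity-index)``, so output is bit-for-bit
deterministic and — crucially for the coupled-comparison tests —
changing one knob (say ``p_share`` or the introgression count) leaves
every other entity's draws untouched.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy import optimize

from .io import (BarcodeSequence, Library, SpecimenRecord, link,
                 write_fasta, write_metadata)

_BASES = "ACGT"

# stream tags (second entry of the RNG entropy list)
_T_TAXONOMY = 1
_T_SHARE = 2
_T_SPECIES_SEQ = 3
_T_DROPOUT = 4
_T_INTROGRESSION = 5
_T_GENUS_SEQ = 6
_T_FAMILY_ROOT = 7
_T_INDIVIDUAL = 8


# ---------------------------------------------------------------------------
# configuration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CountDistribution:
    """A small integer count distribution with finite support.

    kinds: ``fixed`` (value), ``uniform`` (low..high inclusive),
    ``truncated_geometric`` (geometric on low..high with the stated mean).
    """

    kind: str
    value: int = 0
    low: int = 1
    high: int = 1
    mean: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("fixed", "uniform", "truncated_geometric"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind != "fixed" and self.low > self.high:
            raise ValueError("low must be <= high")
        if self.kind == "truncated_geometric" and not (
                self.low < self.mean < self.high):
            raise ValueError("mean must lie strictly inside (low, high)")

    def pmf(self) -> dict[int, float]:
        if self.kind == "fixed":
            return {self.value: 1.0}
        if self.kind == "uniform":
            ks = range(self.low, self.high + 1)
            w = 1.0 / len(ks)
            return {k: w for k in ks}
        q = self._geometric_q()
        ks = np.arange(self.low, self.high + 1)
        w = (1.0 - q) ** (ks - self.low)
        w /= w.sum()
        return dict(zip(ks.tolist(), w.tolist()))

    def _geometric_q(self) -> float:
        ks = np.arange(self.low, self.high + 1)

        def mean_at(q: float) -> float:
            w = (1.0 - q) ** (ks - self.low)
            return float((ks * w).sum() / w.sum())

        return optimize.brentq(
            lambda q: mean_at(q) - self.mean, 1e-9, 1.0 - 1e-9)

    def sample(self, rng: np.random.Generator) -> int:
        pmf = self.pmf()
        ks = list(pmf)
        return int(rng.choice(ks, p=[pmf[k] for k in ks]))

    def expectation(self) -> tuple[float, float]:
        """(mean, variance)."""
        pmf = self.pmf()
        mu = sum(k * w for k, w in pmf.items())
        var = sum((k - mu) ** 2 * w for k, w in pmf.items())
        return mu, var


def fixed(value: int) -> CountDistribution:
    return CountDistribution("fixed", value=value)


def uniform_count(low: int, high: int) -> CountDistribution:
    return CountDistribution("uniform", low=low, high=high)


def truncated_geometric(mean: float, low: int, high: int) -> CountDistribution:
    return CountDistribution("truncated_geometric", low=low, high=high,
                             mean=mean)


@dataclass(frozen=True)
class DropoutSpec:
    """Per-locus recovery-failure model.

    A silica specimen fails with probability ``base``.  A herbarium
    specimen fails with sigmoid(logit(base) + herbarium_penalty +
    age_coefficient * decades-before-anchor); the coefficients are in
    logit units per unit / per decade.
    """

    base: float
    herbarium_penalty: float = 0.0
    age_coefficient: float = 0.0

    def failure_probability(self, source: str, year: Optional[int],
                            anchor_year: int) -> float:
        if not 0.0 <= self.base <= 1.0:
            raise ValueError("base failure probability must be in [0,1]")
        if source != "herbarium":
            return self.base
        if self.base == 0.0:
            return 0.0
        if self.base == 1.0:
            return 1.0
        decades = 0.0 if year is None else (anchor_year - year) / 10.0
        logit = math.log(self.base / (1.0 - self.base))
        logit += self.herbarium_penalty + self.age_coefficient * decades
        return 1.0 / (1.0 + math.exp(-logit))


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the library generator.

    Defaults are a desk-scale analogue of an Arctic-flora-sized library:
    genus and species counts follow truncated geometrics matching a mean
    of ~2.8 species per genus and 5 individuals per species (range 1-27);
    loci default to rbcL (552 bp) and matK (800 bp); dropout defaults give
    ~93 % rbcL and ~85 % silica matK recovery with an age-dependent matK
    decline in herbarium material; 44 % of specimens are herbarium-sourced
    with collection years 1950-2010.
    """

    seed: int = 0
    n_families: int = 10
    genera_per_family: CountDistribution = field(
        default_factory=lambda: uniform_count(3, 5))
    species_per_genus: CountDistribution = field(
        default_factory=lambda: truncated_geometric(2.8, 1, 10))
    individuals_per_species: CountDistribution = field(
        default_factory=lambda: truncated_geometric(5.0, 1, 27))
    loci: tuple[tuple[str, int], ...] = (("rbcL", 552), ("matK", 800))
    genus_divergence: float = 0.02     # substitutions/site genus vs family
    species_divergence: float = 0.005  # species vs genus base
    haplotype_divergence: float = 0.002  # within-species variants
    #: per-locus rate multipliers applied to all divergence scales; matK
    #: evolves ~2.6x faster than rbcL at the congeneric level
    locus_rate_multipliers: tuple[tuple[str, float], ...] = (
        ("rbcL", 1.0), ("matK", 2.6))
    haplotypes_per_species: CountDistribution = field(
        default_factory=lambda: uniform_count(1, 2))
    p_share: float = 0.3
    clade_share_slope: float = 0.0  # added sharing prob per extra congener
    n_introgression_events: int = 0
    introgression_fraction: float = 0.5  # of recipient individuals
    dropout: tuple[tuple[str, DropoutSpec], ...] = (
        ("rbcL", DropoutSpec(base=0.07)),
        ("matK", DropoutSpec(base=0.15, herbarium_penalty=0.0,
                             age_coefficient=0.25)),
    )
    fraction_herbarium: float = 0.44
    anchor_year: int = 2010
    herbarium_year_range: tuple[int, int] = (1950, 2010)
    silica_year_range: tuple[int, int] = (2005, 2010)
    infraspecific_prob: float = 0.06
    infraspecific_distinct_prob: float = 0.17
    p_hybrid: float = 0.005
    indel_prob: float = 0.0  # per individual/locus chance of a 6-bp gap run

    def __post_init__(self) -> None:
        for name, p in (("p_share", self.p_share),
                        ("fraction_herbarium", self.fraction_herbarium),
                        ("infraspecific_prob", self.infraspecific_prob),
                        ("p_hybrid", self.p_hybrid),
                        ("indel_prob", self.indel_prob)):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0,1]")
        for scale in (self.genus_divergence, self.species_divergence,
                      self.haplotype_divergence):
            if scale < 0:
                raise ValueError("divergence scales must be >= 0")
        for _, length in self.loci:
            if length < 1:
                raise ValueError("locus lengths must be >= 1")
        if self.n_families < 1:
            raise ValueError("need at least one family")
        for label, dist in (("genera_per_family", self.genera_per_family),
                            ("species_per_genus", self.species_per_genus),
                            ("individuals_per_species",
                             self.individuals_per_species)):
            if max(dist.pmf()) < 1:
                raise ValueError(f"infeasible config: {label} cannot "
                                 "produce a positive count")

    @property
    def locus_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.loci)

    def rate_multiplier(self, locus: str) -> float:
        for name, mult in self.locus_rate_multipliers:
            if name == locus:
                return mult
        return 1.0

    def dropout_for(self, locus: str) -> DropoutSpec:
        for name, spec in self.dropout:
            if name == locus:
                return spec
        return DropoutSpec(base=0.0)

    def share_probability(self, genus_size: int) -> float:
        p = self.p_share + self.clade_share_slope * max(genus_size - 1, 0)
        return min(max(p, 0.0), 1.0)


# ---------------------------------------------------------------------------
# ground truth
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class IntrogressionEvent:
    donor_species: str
    recipient_species: str
    recipient_individuals: tuple[str, ...]


@dataclass
class GroundTruth:
    """Everything the generator decided, for oracle-grade verification."""

    config: SyntheticConfig
    #: species binomial -> genus, family
    species_parent: dict[str, tuple[str, str]]
    #: (species, locus) -> tuple of haplotype strings in its pool
    species_haplotypes: dict[tuple[str, str], tuple[str, ...]]
    #: genus -> set of species that adopted the shared pool haplotype
    pool_sharers: dict[str, set[str]]
    #: (sample_id, locus) -> generated haplotype string (post-introgression)
    individual_haplotype: dict[tuple[str, str], str]
    #: (sample_id, locus) -> True when the locus failed to sequence
    dropout: dict[tuple[str, str], bool]
    introgression_events: list[IntrogressionEvent]
    #: sample_id -> species binomial ("" for specimens above species rank)
    individual_species: dict[str, str]
    #: sample_ids flagged as putative hybrids
    hybrids: set[str]

    def surviving_haplotypes(self, locus: str,
                             exclude_hybrids: bool = True
                             ) -> dict[str, set[str]]:
        """haplotype string -> set of species, over sequenced individuals."""
        out: dict[str, set[str]] = {}
        for (sid, loc), hap in self.individual_haplotype.items():
            if loc != locus or self.dropout[(sid, loc)]:
                continue
            if exclude_hybrids and sid in self.hybrids:
                continue
            sp = self.individual_species[sid]
            if sp:
                out.setdefault(hap, set()).add(sp)
        return out

    def unresolved_species(self, locus: str) -> set[str]:
        """Species sharing a surviving haplotype with another species."""
        bad: set[str] = set()
        for _, species in self.surviving_haplotypes(locus).items():
            if len(species) > 1:
                bad |= species
        return bad

    def sampled_species(self, locus: Optional[str] = None) -> set[str]:
        """Species with >= 1 sequenced non-hybrid individual (at a locus)."""
        out: set[str] = set()
        for sid, sp in self.individual_species.items():
            if not sp or sid in self.hybrids:
                continue
            loci = self.config.locus_names if locus is None else (locus,)
            if any(not self.dropout[(sid, loc)] for loc in loci):
                out.add(sp)
        return out

    def unresolved_fraction(self, locus: str) -> float:
        sampled = self.sampled_species(locus)
        if not sampled:
            return math.nan
        return len(self.unresolved_species(locus) & sampled) / len(sampled)


# ---------------------------------------------------------------------------
# sequence helpers
# ---------------------------------------------------------------------------


def _random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def _mutate(codes: np.ndarray, n_subs: int,
            rng: np.random.Generator) -> np.ndarray:
    """Apply n substitutions at distinct sites, transition:transversion 2:1."""
    out = codes.copy()
    if n_subs == 0:
        return out
    n_subs = min(n_subs, out.size)
    sites = rng.choice(out.size, size=n_subs, replace=False)
    for site in sites:
        base = out[site]
        if rng.random() < 2.0 / 3.0:  # transition: flip within parity class
            out[site] = base ^ 2
        else:  # one of the two transversions
            out[site] = (base + (1 if rng.random() < 0.5 else 3)) % 4
    return out


def _decode(codes: np.ndarray) -> str:
    return "".join(_BASES[c] for c in codes)


class _Registry:
    """Per-(family, locus) haplotype registry enforcing cross-species
    distinctness; within-owner duplicates are allowed."""

    def __init__(self) -> None:
        self._owner: dict[tuple[str, str, str], str] = {}

    def claim(self, family: str, locus: str, codes: np.ndarray, owner: str,
              rng: np.random.Generator) -> np.ndarray:
        key = (family, locus, _decode(codes))
        while key in self._owner and self._owner[key] != owner:
            codes = _mutate(codes, 1, rng)
            key = (family, locus, _decode(codes))
        self._owner[key] = owner
        return codes


# ---------------------------------------------------------------------------
# the generator
# ---------------------------------------------------------------------------


def _rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([seed, *path])


def generate_library(config: SyntheticConfig
                     ) -> tuple[list[SpecimenRecord], list[BarcodeSequence],
                                GroundTruth]:
    """Generate a barcode library plus its complete ground truth.

    Deterministic given ``config.seed``; see the module docstring for the
    stream-coupling guarantees.
    """
    seed = config.seed
    registry = _Registry()
    records: list[SpecimenRecord] = []
    sequences: list[BarcodeSequence] = []

    species_parent: dict[str, tuple[str, str]] = {}
    species_haps: dict[tuple[str, str], tuple[str, ...]] = {}
    pool_sharers: dict[str, set[str]] = {}
    individual_hap: dict[tuple[str, str], str] = {}
    dropout: dict[tuple[str, str], bool] = {}
    individual_species: dict[str, str] = {}
    hybrids: set[str] = set()
    #: species -> list of its sample_ids (for introgression targeting)
    members: dict[str, list[str]] = {}
    #: species -> per-locus pool as code arrays (index 0 is the base hap)
    pools: dict[str, dict[str, list[np.ndarray]]] = {}
    genus_of_family: dict[str, str] = {}

    sp_idx = 0
    ind_idx = 0
    genus_idx = 0
    genus_species: dict[str, list[str]] = {}

    for f in range(config.n_families):
        family = f"Fam{f + 1:02d}"
        rng_tax = _rng(seed, _T_TAXONOMY, f)
        rng_root = _rng(seed, _T_FAMILY_ROOT, f)
        roots = {name: _random_sequence(length, rng_root)
                 for name, length in config.loci}
        n_genera = config.genera_per_family.sample(rng_tax)
        for g in range(n_genera):
            genus = f"Genus{f + 1:02d}{chr(ord('a') + g)}"
            genus_of_family[genus] = family
            rng_gen = _rng(seed, _T_GENUS_SEQ, genus_idx)
            genus_idx += 1
            genus_base = {}
            for name, length in config.loci:
                n_subs = rng_gen.binomial(
                    length, min(config.genus_divergence
                                * config.rate_multiplier(name), 1.0))
                codes = _mutate(roots[name], n_subs, rng_gen)
                codes = registry.claim(family, name, codes,
                                       f"pool:{genus}", rng_gen)
                genus_base[name] = codes
            n_species = config.species_per_genus.sample(rng_tax)
            share_p = config.share_probability(n_species)
            pool_sharers[genus] = set()
            genus_species[genus] = []
            for s in range(n_species):
                species = f"{genus} sp{s + 1:02d}"
                species_parent[species] = (genus, family)
                genus_species[genus].append(species)
                members[species] = []
                shares = _rng(seed, _T_SHARE, sp_idx).random() < share_p
                rng_sp = _rng(seed, _T_SPECIES_SEQ, sp_idx)
                sp_idx += 1
                pool: dict[str, list[np.ndarray]] = {}
                if shares:
                    pool_sharers[genus].add(species)
                    for name, _ in config.loci:
                        pool[name] = [genus_base[name]]
                else:
                    n_haps = config.haplotypes_per_species.sample(rng_sp)
                    for name, length in config.loci:
                        n_subs = rng_sp.binomial(
                            length, min(config.species_divergence
                                        * config.rate_multiplier(name), 1.0))
                        base = _mutate(genus_base[name], n_subs, rng_sp)
                        base = registry.claim(family, name, base,
                                              species, rng_sp)
                        haps = [base]
                        for _ in range(n_haps - 1):
                            nv = rng_sp.binomial(
                                length, min(config.haplotype_divergence
                                            * config.rate_multiplier(name),
                                            1.0))
                            var = _mutate(base, max(nv, 1), rng_sp)
                            var = registry.claim(family, name, var,
                                                 species, rng_sp)
                            haps.append(var)
                        pool[name] = haps
                pools[species] = pool

                n_ind = config.individuals_per_species.sample(rng_tax)
                has_infra = (not shares and n_ind >= 2
                             and rng_sp.random() < config.infraspecific_prob)
                infra_distinct = (has_infra and rng_sp.random()
                                  < config.infraspecific_distinct_prob)
                infra_pool: dict[str, np.ndarray] = {}
                if infra_distinct:
                    for name, length in config.loci:
                        var = _mutate(pool[name][0], 1, rng_sp)
                        var = registry.claim(family, name, var,
                                             species, rng_sp)
                        infra_pool[name] = var
                        pool[name] = pool[name] + [var]
                species_haps.update(
                    {(species, name): tuple(_decode(h) for h in pool[name])
                     for name, _ in config.loci})

                for k in range(n_ind):
                    sample_id = f"S{ind_idx + 1:05d}"
                    rng_ind = _rng(seed, _T_INDIVIDUAL, ind_idx)
                    rng_drop = _rng(seed, _T_DROPOUT, ind_idx)
                    ind_idx += 1
                    is_hybrid = rng_ind.random() < config.p_hybrid
                    herbarium = rng_ind.random() < config.fraction_herbarium
                    if herbarium:
                        lo, hi = config.herbarium_year_range
                    else:
                        lo, hi = config.silica_year_range
                    year = int(rng_ind.integers(lo, hi + 1))
                    infra = None
                    use_infra_hap = False
                    if has_infra:
                        second = k >= (n_ind + 1) // 2
                        infra = ("subsp.", "beta" if second else "alpha")
                        use_infra_hap = infra_distinct and second
                    rec = SpecimenRecord(
                        sample_id=sample_id, family=family, genus=genus,
                        species=f"sp{s + 1:02d}", infraspecific=infra,
                        is_hybrid=is_hybrid,
                        source="herbarium" if herbarium else "silica",
                        collection_year=year)
                    records.append(rec)
                    members[species].append(sample_id)
                    individual_species[sample_id] = species
                    if is_hybrid:
                        hybrids.add(sample_id)
                    for name, length in config.loci:
                        haps = pool[name]
                        if use_infra_hap:
                            codes = infra_pool[name]
                        else:
                            n_base = len(haps) - (1 if infra_distinct else 0)
                            codes = haps[int(rng_ind.integers(n_base))]
                        hap_str = _decode(codes)
                        individual_hap[(sample_id, name)] = hap_str
                        spec = config.dropout_for(name)
                        p_fail = spec.failure_probability(
                            rec.source, year, config.anchor_year)
                        failed = rng_drop.random() < p_fail
                        dropout[(sample_id, name)] = failed
                        if config.indel_prob > 0 and not failed:
                            if rng_ind.random() < config.indel_prob:
                                start = int(rng_ind.integers(
                                    0, max(length - 6, 1)))
                                hap_str = (hap_str[:start] + "------"
                                           + hap_str[start + 6:])
                                individual_hap[(sample_id, name)] = hap_str
                        if not failed:
                            sequences.append(BarcodeSequence(
                                sample_id=sample_id, locus=name,
                                residues=hap_str, aligned=True))

    events = _apply_introgression(
        config, genus_species, members, pools, individual_hap,
        dropout, sequences)

    truth = GroundTruth(
        config=config, species_parent=species_parent,
        species_haplotypes=species_haps, pool_sharers=pool_sharers,
        individual_haplotype=individual_hap, dropout=dropout,
        introgression_events=events, individual_species=individual_species,
        hybrids=hybrids)
    return records, sequences, truth


def _apply_introgression(config, genus_species, members, pools,
                         individual_hap, dropout, sequences
                         ) -> list[IntrogressionEvent]:
    """Overwrite recipient individuals' plastid with the donor's base hap."""
    events: list[IntrogressionEvent] = []
    if config.n_introgression_events == 0:
        return events
    eligible = sorted(g for g, sps in genus_species.items() if len(sps) >= 2)
    if not eligible:
        raise ValueError("introgression requested but no genus has >= 2 "
                         "species")
    by_id = {(s.sample_id, s.locus): i for i, s in enumerate(sequences)}
    used: set[str] = set()
    for e in range(config.n_introgression_events):
        rng = _rng(config.seed, _T_INTROGRESSION, e)
        pick_from = [g for g in eligible if g not in used] or eligible
        genus = pick_from[int(rng.integers(len(pick_from)))]
        used.add(genus)
        donor, recipient = (str(x) for x in rng.choice(
            genus_species[genus], size=2, replace=False))
        recip_ids = members[recipient]
        n_recip = max(1, math.ceil(
            config.introgression_fraction * len(recip_ids)))
        chosen = sorted(
            str(s) for s in rng.choice(recip_ids, size=n_recip,
                                       replace=False))
        # capture a haplotype an actual donor individual carries (and,
        # when possible, one present in the sequenced library)
        donor_ind = next(
            (sid for sid in members[donor]
             if all(not dropout[(sid, name)] for name, _ in config.loci)),
            members[donor][0])
        for sid in chosen:
            for name, _ in config.loci:
                hap = individual_hap[(donor_ind, name)]
                individual_hap[(sid, name)] = hap
                if not dropout[(sid, name)]:
                    idx = by_id[(sid, name)]
                    old = sequences[idx]
                    sequences[idx] = BarcodeSequence(
                        sample_id=old.sample_id, locus=old.locus,
                        residues=hap, aligned=True)
        events.append(IntrogressionEvent(
            donor_species=donor, recipient_species=recipient,
            recipient_individuals=tuple(chosen)))
    return events


def generated_library(config: SyntheticConfig) -> tuple[Library, GroundTruth]:
    """Convenience wrapper: generate and link in one call."""
    records, sequences, truth = generate_library(config)
    return link(records, sequences), truth


# ---------------------------------------------------------------------------
# analytic companion
# ---------------------------------------------------------------------------


def expected_unresolved_fraction(config: SyntheticConfig
                                 ) -> tuple[float, float]:
    """Closed-form expectation (and sd) of the unresolved-species fraction.

    Valid only in the *simple regime*: independent per-species sharing
    draws and nothing else creating or destroying identity — no
    introgression, no clade-structured sharing, no hybrids, no dropout.
    A species is unresolved iff it adopted the genus pool haplotype along
    with at least one congener, so within a genus of k species the
    unresolved count is j·1[j >= 2] with j ~ Binomial(k, p_share).

    The returned sd is for the *fraction* over one generated library and
    accounts for the genus-level clustering of the sharing draws (a
    species-level binomial band would be mis-calibrated): means, variances
    and the numerator/denominator covariance are enumerated exactly over
    the genus-size pmf, then combined with the delta method for the ratio.
    """
    if config.n_introgression_events != 0:
        raise ValueError("simple regime requires no introgression")
    if config.clade_share_slope != 0:
        raise ValueError("simple regime requires constant p_share")
    if config.p_hybrid != 0:
        raise ValueError("simple regime requires p_hybrid = 0")
    for name, _ in config.loci:
        if config.dropout_for(name).base != 0:
            raise ValueError("simple regime requires zero dropout")

    p = config.p_share
    from math import comb

    k_pmf = config.species_per_genus.pmf()
    # per-genus moments of (N=k, U=unresolved count)
    e_n = var_n = e_u = e_u2 = e_un = 0.0
    for k, wk in k_pmf.items():
        eu_k = eu2_k = 0.0
        for j in range(k + 1):
            pj = comb(k, j) * p ** j * (1 - p) ** (k - j)
            u = j if j >= 2 else 0
            eu_k += pj * u
            eu2_k += pj * u * u
        e_n += wk * k
        var_n += wk * k * k
        e_u += wk * eu_k
        e_u2 += wk * eu2_k
        e_un += wk * eu_k * k
    var_n -= e_n ** 2
    var_u = e_u2 - e_u ** 2
    cov_un = e_un - e_u * e_n

    m_mu, m_var = config.genera_per_family.expectation()
    g_mu = config.n_families * m_mu
    g_var = config.n_families * m_var
    # compound sums over a random number of genera
    tot_u = g_mu * e_u
    tot_n = g_mu * e_n
    var_tot_u = g_mu * var_u + g_var * e_u ** 2
    var_tot_n = g_mu * var_n + g_var * e_n ** 2
    cov_tot = g_mu * cov_un + g_var * e_u * e_n

    mean_f = tot_u / tot_n
    var_f = (var_tot_u - 2 * mean_f * cov_tot + mean_f ** 2 * var_tot_n) \
        / tot_n ** 2
    return mean_f, math.sqrt(max(var_f, 0.0))


# ---------------------------------------------------------------------------
# fixtures on disk
# ---------------------------------------------------------------------------


def write_fixture(records: Sequence[SpecimenRecord],
                  sequences: Sequence[BarcodeSequence],
                  truth: GroundTruth, directory: str | Path) -> None:
    """Write the library in exactly the formats the readers consume.

    One FASTA per (family, locus), one metadata table, and ground-truth
    tables (per-individual haplotypes/dropout and introgression events).
    Output is byte-identical for identical configs.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    fam_of = {r.sample_id: r.family for r in records}
    by_file: dict[tuple[str, str], list[BarcodeSequence]] = {}
    for s in sorted(sequences, key=lambda s: (s.sample_id, s.locus)):
        by_file.setdefault((fam_of[s.sample_id], s.locus), []).append(s)
    for (family, locus), seqs in sorted(by_file.items()):
        write_fasta(seqs, directory / f"{family}_{locus}.fasta")
    write_metadata(sorted(records, key=lambda r: r.sample_id),
                   directory / "metadata.tsv")
    with open(directory / "ground_truth_haplotypes.tsv", "w") as fh:
        fh.write("sample_id\tlocus\tdropped\thaplotype\n")
        for (sid, locus) in sorted(truth.individual_haplotype):
            fh.write(f"{sid}\t{locus}\t"
                     f"{int(truth.dropout[(sid, locus)])}\t"
                     f"{truth.individual_haplotype[(sid, locus)]}\n")
    with open(directory / "ground_truth_events.tsv", "w") as fh:
        fh.write("donor_species\trecipient_species\trecipient_individuals\n")
        for ev in truth.introgression_events:
            fh.write(f"{ev.donor_species}\t{ev.recipient_species}\t"
                     f"{','.join(ev.recipient_individuals)}\n")
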