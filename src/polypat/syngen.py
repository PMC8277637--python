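"""Exact inbreeding dynamics of synthetic generations.

A population is a set of founder classes. Each class carries a frequency and
an N_f x N_f matrix J where J[f, g] is the probability that the class's
ordered allele pair (maternal copy, paternal copy) originates from founders
(f, g). Founders are fully inbred and mutually unrelated, so identity by
descent is equivalent to identity of founder origin; the inbreeding
coefficient of a class is the trace of J and the coancestry of two distinct
classes is the dot product of their allele-origin marginals.

Generations advance deterministically (infinite population within classes,
no drift): a mother class contributes selfed offspring with probability
1 - C and crossed offspring otherwise, with the donor class drawn
proportional to class frequency times class pollen weight. Pollen weights
derive from per-founder weights through a single explicit locus whose zero
expression can be recessive (a plant sheds no viable cross pollen only if
both alleles stem from zero-weight founders) or dominant (one such allele
suffices). A mother class crossing with its own clonal class produces the
same allele-origin matrix as selfing, so the "sole donor only selfs" reading
of the extreme scenario is automatic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError

MERGE_DECIMALS = 12


@dataclass
class FounderClass:
    """A fraction of the population sharing one joint founder-origin law."""

    freq: float
    J: np.ndarray

    def __post_init__(self):
        self.J = np.asarray(self.J, dtype=float)
        if self.J.ndim != 2 or self.J.shape[0] != self.J.shape[1]:
            raise ConfigurationError("J must be a square matrix")
        if self.freq < 0 or (self.J < -1e-15).any():
            raise ConfigurationError("negative frequency or J entry")
        if abs(self.J.sum() - 1.0) > 1e-9:
            raise ConfigurationError("J entries must sum to 1")

    @property
    def F(self) -> float:
        """Inbreeding coefficient: probability both alleles share a founder."""
        return float(np.trace(self.J))

    @property
    def marginal(self) -> np.ndarray:
        """Founder-origin distribution of a random allele (= of a gamete)."""
        return (self.J.sum(axis=1) + self.J.sum(axis=0)) / 2.0


@dataclass
class SynPopulation:
    n_founders: int
    classes: list
    generation: int = 0

    def validate(self) -> None:
        total = sum(c.freq for c in self.classes)
        if abs(total - 1.0) > 1e-9:
            raise ConfigurationError(f"class frequencies sum to {total}, not 1")
        for c in self.classes:
            if c.J.shape[0] != self.n_founders:
                raise ConfigurationError("class founder dimension mismatch")


@dataclass
class SynMatingModel:
    """Population-level mating parameters for advancing Syn generations."""

    cross_rate: float = 0.5  # C: probability a seed is cross-flower pollinated
    founder_weights: Optional[np.ndarray] = None  # per-founder pollen weight
    null_mode: str = "recessive"  # inheritance of zero pollen weight
    external_pollen: bool = False  # cross pollen from fresh unrelated founders

    def __post_init__(self):
        if not 0.0 <= self.cross_rate <= 1.0:
            raise ConfigurationError("cross_rate must be in [0, 1]")
        if self.null_mode not in ("recessive", "dominant"):
            raise ConfigurationError(f"unknown null mode {self.null_mode!r}")
        if self.founder_weights is not None:
            self.founder_weights = np.asarray(self.founder_weights, dtype=float)
            if (self.founder_weights < 0).any():
                raise ConfigurationError("founder weights must be nonnegative")

    def class_weight(self, J: np.ndarray) -> float:
        """Expected pollen weight of a plant of the class.

        With per-founder weights w the plant-level weight of founder origins
        (f, g) is max(w_f, w_g) under recessive zero expression and
        min(w_f, w_g) under dominant zero expression; both reduce to the
        common weight when weights are equal.
        """
        if self.founder_weights is None:
            return 1.0
        w = self.founder_weights
        pair = (
            np.maximum.outer(w, w)
            if self.null_mode == "recessive"
            else np.minimum.outer(w, w)
        )
        return float((J * pair).sum())


def mean_inbreeding(population: SynPopulation) -> float:
    return float(sum(c.freq * c.F for c in population.classes))


def coancestry(a: FounderClass, b: FounderClass, same_individual: bool = False) -> float:
    """IBD probability of random alleles from the two classes.

    For the same individual this is (1 + F) / 2; for distinct individuals the
    dot product of the founder-origin marginals (founders fully inbred and
    unrelated).
    """
    if same_individual:
        return (1.0 + a.F) / 2.0
    return float(a.marginal @ b.marginal)


def selfed_J(J: np.ndarray) -> np.ndarray:
    """Offspring origin matrix under selfing: both gametes are uniform draws
    from the parent's ordered allele pair."""
    r = J.sum(axis=1)
    c = J.sum(axis=0)
    return (np.diag(r) + np.diag(c) + J + J.T) / 4.0


def crossed_J(mother_marginal: np.ndarray, donor_marginal: np.ndarray) -> np.ndarray:
    """Offspring origin matrix for a cross: maternal gamete x donor gamete."""
    return np.outer(mother_marginal, donor_marginal)


def idealized_f_trajectory(C: float, generations: int):
    """Inbreeding recursion under no P variation and unrelated cross pollen.

    F_0 = 1, F_{t+1} = (1 - C)(1 + F_t) / 2; the fixed point is
    (1 - C) / (1 + C). Returns (list F_0..F_n, F_inf).
    """
    if not 0.0 <= C <= 1.0:
        raise ConfigurationError("C must be in [0, 1]")
    traj = [1.0]
    for _ in range(generations):
        traj.append((1.0 - C) * (1.0 + traj[-1]) / 2.0)
    f_inf = (1.0 - C) / (1.0 + C)
    return traj, f_inf


def make_scenario(
    name: Union[str, SynMatingModel], n_founders: int = 8
) -> tuple:
    """Extreme scenarios: 'one' = equal pollen weights for all components,
    'two' = a single component donates all cross pollen.

    Syn-0 consists of ``n_founders`` fully inbred, unrelated components with
    equal frequencies; C is 0.5 for every class and the donor pool includes
    the mother's own genotype (the intra-genotype share of cross events is
    1/n under scenario one).
    """
    classes = [
        FounderClass(1.0 / n_founders, np.outer(_e(i, n_founders), _e(i, n_founders)))
        for i in range(n_founders)
    ]
    pop = SynPopulation(n_founders=n_founders, classes=classes, generation=0)
    if isinstance(name, SynMatingModel):
        return pop, name
    if name == "one":
        model = SynMatingModel(cross_rate=0.5, founder_weights=np.ones(n_founders))
    elif name == "two":
        w = np.zeros(n_founders)
        w[-1] = 1.0
        model = SynMatingModel(cross_rate=0.5, founder_weights=w)
    else:
        raise ConfigurationError(f"unknown scenario {name!r}")
    return pop, model


def _e(i: int, n: int) -> np.ndarray:
    v = np.zeros(n)
    v[i] = 1.0
    return v


def _merge(classes: list, n_founders: int) -> list:
    merged: dict = {}
    for c in classes:
        if c.freq <= 0:
            continue
        key = np.ascontiguousarray(np.round(c.J, MERGE_DECIMALS)).tobytes()
        if key in merged:
            merged[key] = FounderClass(merged[key].freq + c.freq, merged[key].J)
        else:
            merged[key] = c
    return list(merged.values())


def advance_generation(
    population: SynPopulation, model: SynMatingModel
) -> SynPopulation:
    """One generation of partially allogamous propagation."""
    population.validate()
    C = model.cross_rate
    n_f = population.n_founders

    if model.external_pollen:
        # fresh unrelated founder supplies all cross pollen (theta = 0)
        n_new = n_f + 1
        donor_marginals = [_e(n_f, n_new)]
        donor_probs = np.array([1.0])
        expand = True
    else:
        weights = np.array(
            [c.freq * model.class_weight(c.J) for c in population.classes]
        )
        total = weights.sum()
        if C > 0 and total <= 0:
            raise ConfigurationError(
                "cross-fertilization requested but all pollen weights are zero"
            )
        donor_probs = weights / total if total > 0 else weights
        donor_marginals = [c.marginal for c in population.classes]
        n_new = n_f
        expand = False

    offspring = []
    for mother in population.classes:
        J_m = mother.J
        p_m = mother.marginal
        if expand:
            J_m = _pad(J_m, n_new)
            p_m = np.concatenate([p_m, [0.0]])
        if C < 1.0:
            offspring.append(FounderClass(mother.freq * (1.0 - C), selfed_J(J_m)))
        if C > 0.0:
            for q, p_d in zip(donor_probs, donor_marginals):
                if q <= 0:
                    continue
                if expand:
                    J_x = crossed_J(p_m, p_d)
                else:
                    J_x = crossed_J(p_m, p_d)
                offspring.append(FounderClass(mother.freq * C * q, J_x))

    classes = _merge(offspring, n_new)
    out = SynPopulation(
        n_founders=n_new, classes=classes, generation=population.generation + 1
    )
    out.validate()
    return out


def _pad(J: np.ndarray, n: int) -> np.ndarray:
    out = np.zeros((n, n))
    out[: J.shape[0], : J.shape[1]] = J
    return out


def mean_genetic_c(population: SynPopulation, model: SynMatingModel) -> float:
    """Population mean genetic degree of cross-fertilization.

    A cross event with a donor of the mother's own class counts as
    intra-genotype (genetically selfing); only crosses with a different class
    are genetic cross-fertilization. Meaningful when classes are clonal
    (e.g. Syn-0), where class identity coincides with genotype identity.
    """
    population.validate()
    if model.external_pollen:
        return model.cross_rate
    weights = np.array(
        [c.freq * model.class_weight(c.J) for c in population.classes]
    )
    total = weights.sum()
    if total <= 0:
        return 0.0
    donor_probs = weights / total
    keys = [
        np.ascontiguousarray(np.round(c.J, MERGE_DECIMALS)).tobytes()
        for c in population.classes
    ]
    value = 0.0
    for i, mother in enumerate(population.classes):
        inter = sum(
            q for j, q in enumerate(donor_probs) if keys[j] != keys[i]
        )
        value += mother.freq * model.cross_rate * inter
    return float(value)


def trajectory(
    population: SynPopulation, model: SynMatingModel, generations: int
) -> pd.DataFrame:
    """Mean inbreeding across generations; row 0 is the starting population."""
    rows = [(population.generation, mean_inbreeding(population),
             len(population.classes))]
    pop = population
    for _ in range(generations):
        pop = advance_generation(pop, model)
        rows.append((pop.generation, mean_inbreeding(pop), len(pop.classes)))
    return pd.DataFrame(rows, columns=["generation", "mean_F", "n_classes"])
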