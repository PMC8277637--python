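"""Synthetic polycross generator.

Produces a plant roster for a block design, samples mating events per seed
(self vs cross-flower pollen, donor genotype and plant), transmits alleles
Mendelian-style at the panel's biallelic SNPs, and applies genotyping-call
noise. Ground truth is kept alongside so downstream estimators can be
validated against known mating parameters.

Mating model per seed of a mother plant of genotype g:

* with probability ``1 - X_g`` the seed is autogamous/geitonogamous self
  (the two are deliberately not separated -- they are indistinguishable in
  the data this pipeline emulates);
* otherwise the seed results from cross-flower pollen whose donor genotype
  is sampled proportional to ``w_d * K[g, d]`` over the candidate donors
  (the mother's own genotype included iff ``include_intra``), and the donor
  plant uniformly among that genotype's other plants of the same year.

Events are labelled self / intra / inter; only inter events are
cross-fertilization in the genetic sense.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DataError
from .panel import GenotypePanel

TRUTH_COLUMNS = [
    "seed_id", "mother_plant", "mother_genotype", "block", "year",
    "event", "donor_genotype", "donor_plant",
]
CALL_META_COLUMNS = ["seed_id", "mother_plant", "block", "year"]


@dataclass
class PolycrossDesign:
    """Block design: every genotype appears with the same number of plants in
    every block, replicated over years."""

    genotypes: Sequence[str] = tuple(f"G{i + 1}" for i in range(8))
    n_blocks: int = 8
    plants_per_genotype_per_block: int = 8
    years: Sequence[int] = (1,)

    def __post_init__(self):
        self.genotypes = tuple(self.genotypes)
        self.years = tuple(self.years)
        if min(self.n_blocks, self.plants_per_genotype_per_block) < 1:
            raise ConfigurationError("design dimensions must be positive")
        if not self.genotypes or not self.years:
            raise ConfigurationError("design needs >=1 genotype and >=1 year")
        if len(self.genotypes) != 8:
            warnings.warn(
                f"polycross has {len(self.genotypes)} genotypes; the engine is "
                "generic but the reference design uses 8",
                stacklevel=2,
            )

    @property
    def n_plants(self) -> int:
        return (
            len(self.genotypes)
            * self.n_blocks
            * self.plants_per_genotype_per_block
            * len(self.years)
        )

    def roster(self) -> pd.DataFrame:
        """Deterministic plant roster: one row per plant."""
        rows = []
        for year in self.years:
            for block in range(1, self.n_blocks + 1):
                for g in self.genotypes:
                    for i in range(1, self.plants_per_genotype_per_block + 1):
                        rows.append(
                            (f"Y{year}_B{block}_{g}_P{i}", g, block, year)
                        )
        return pd.DataFrame(rows, columns=["plant_id", "genotype", "block", "year"])


def make_design(
    genotypes: Optional[Sequence[str]] = None,
    n_blocks: int = 8,
    plants_per_genotype_per_block: int = 8,
    years: Sequence[int] = (1,),
) -> PolycrossDesign:
    if genotypes is None:
        genotypes = tuple(f"G{i + 1}" for i in range(8))
    return PolycrossDesign(
        genotypes=genotypes,
        n_blocks=n_blocks,
        plants_per_genotype_per_block=plants_per_genotype_per_block,
        years=years,
    )


def _logit(p):
    return np.log(p / (1.0 - p))


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class MatingParams:
    """Genotype-specific mating parameters.

    ``cross_flower_rate`` is X_g, the probability that a seed results from
    cross-flower pollen; the realized genetic degree of cross-fertilization
    is X_g times the inter-genotype share of the donor pool. ``year_effects``
    are additive shifts of logit(X_g) per year.
    """

    cross_flower_rate: Union[float, Mapping[str, float]] = 0.5
    donor_weight: Union[float, Mapping[str, float]] = 1.0
    compatibility: Optional[pd.DataFrame] = None  # K[mother, donor], default 1
    include_intra: bool = True
    year_effects: Optional[Mapping[int, float]] = None

    def rate_for(self, genotype: str, year: int) -> float:
        x = (
            self.cross_flower_rate
            if np.isscalar(self.cross_flower_rate)
            else self.cross_flower_rate[genotype]
        )
        if not 0.0 <= x <= 1.0:
            raise ConfigurationError(
                f"cross_flower_rate for {genotype} must be in [0, 1], got {x}"
            )
        if self.year_effects:
            shift = self.year_effects.get(year, 0.0)
            if shift != 0.0:
                if x in (0.0, 1.0):
                    return x  # degenerate rates stay fixed
                x = float(_expit(_logit(x) + shift))
        return float(x)

    def weight_for(self, genotype: str) -> float:
        w = (
            self.donor_weight
            if np.isscalar(self.donor_weight)
            else self.donor_weight[genotype]
        )
        if w < 0:
            raise ConfigurationError(
                f"donor_weight for {genotype} must be nonnegative, got {w}"
            )
        return float(w)

    def donor_probs(self, mother: str, genotypes: Sequence[str]) -> np.ndarray:
        """Donor-genotype sampling distribution for one mother genotype."""
        probs = np.zeros(len(genotypes))
        for j, d in enumerate(genotypes):
            if d == mother and not self.include_intra:
                continue
            k = 1.0
            if self.compatibility is not None:
                k = float(self.compatibility.loc[mother, d])
                if k < 0:
                    raise ConfigurationError(
                        f"compatibility[{mother}, {d}] must be nonnegative"
                    )
            probs[j] = self.weight_for(d) * k
        total = probs.sum()
        if total <= 0:
            raise ConfigurationError(
                f"all donor weights are zero for mother genotype {mother}"
            )
        return probs / total


@dataclass
class NoiseModel:
    """KASP-style call noise: a call goes missing, or one of its two bases is
    substituted by the marker's other allele."""

    missing_rate: float = 0.0
    error_rate: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self):
        for name in ("missing_rate", "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")


def simulate_matings(
    design: PolycrossDesign,
    params: MatingParams,
    seeds_per_plant: int = 12,
    rng_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Sample the mating event of every seed; returns the ground-truth table."""
    rng = np.random.default_rng(rng_seed)
    roster = design.roster()
    genotypes = list(design.genotypes)
    g_index = {g: j for j, g in enumerate(genotypes)}

    # plant ids per (year, genotype) for donor-plant sampling
    plants_by = {
        key: grp["plant_id"].to_numpy()
        for key, grp in roster.groupby(["year", "genotype"], sort=False)
    }
    donor_prob = {g: params.donor_probs(g, genotypes) for g in genotypes}

    n_seeds = len(roster) * seeds_per_plant
    mother_plant = np.repeat(roster["plant_id"].to_numpy(), seeds_per_plant)
    mother_geno = np.repeat(roster["genotype"].to_numpy(), seeds_per_plant)
    block = np.repeat(roster["block"].to_numpy(), seeds_per_plant)
    year = np.repeat(roster["year"].to_numpy(), seeds_per_plant)

    rate = np.array(
        [params.rate_for(g, y) for g, y in zip(mother_geno, year)]
    )
    is_cross = rng.random(n_seeds) < rate

    donor_geno = mother_geno.copy()
    donor_plant = mother_plant.copy()
    event = np.where(is_cross, "", "self").astype(object)

    cross_idx = np.flatnonzero(is_cross)
    if cross_idx.size:
        # donor genotype, grouped by mother genotype for vectorized sampling
        donor_j = np.empty(cross_idx.size, dtype=int)
        mg_codes = np.array([g_index[g] for g in mother_geno[cross_idx]])
        for g in genotypes:
            sel = np.flatnonzero(mg_codes == g_index[g])
            if sel.size:
                donor_j[sel] = rng.choice(
                    len(genotypes), size=sel.size, p=donor_prob[g]
                )
        for pos, seed_i in enumerate(cross_idx):
            d = genotypes[donor_j[pos]]
            pool = plants_by[(year[seed_i], d)]
            if d == mother_geno[seed_i]:
                # uniform among the genotype's *other* plants
                if len(pool) < 2:
                    raise ConfigurationError(
                        "intra-genotype cross sampled but the genotype has a "
                        "single plant; set include_intra=False or add plants"
                    )
                k = rng.integers(len(pool) - 1)
                own = np.flatnonzero(pool == mother_plant[seed_i])[0]
                if k >= own:
                    k += 1
                event[seed_i] = "intra"
            else:
                k = rng.integers(len(pool))
                event[seed_i] = "inter"
            donor_geno[seed_i] = d
            donor_plant[seed_i] = pool[k]

    truth = pd.DataFrame(
        {
            "seed_id": [f"S{i + 1:06d}" for i in range(n_seeds)],
            "mother_plant": mother_plant,
            "mother_genotype": mother_geno,
            "block": block,
            "year": year,
            "event": event,
            "donor_genotype": donor_geno,
            "donor_plant": donor_plant,
        }
    )
    return truth


def genotype_offspring(
    truth: pd.DataFrame,
    panel: GenotypePanel,
    noise: Optional[NoiseModel] = None,
    rng_seed: Optional[int] = None,
) -> pd.DataFrame:
    """Mendelian transmission at every panel marker, then call noise.

    Each offspring call is one allele drawn uniformly from the mother's call
    plus one from the father's, reported as an unordered pair; with
    probability ``missing_rate`` the call is NA, else with probability
    ``error_rate`` one of its two bases is substituted by the marker's other
    allele. The truth table is left untouched.
    """
    noise = noise or NoiseModel()
    if rng_seed is None:
        rng_seed = noise.seed
    rng = np.random.default_rng(rng_seed)
    n = len(truth)

    calls = pd.DataFrame(
        {
            "seed_id": truth["seed_id"].to_numpy(),
            "mother_plant": truth["mother_plant"].to_numpy(),
            "block": truth["block"].to_numpy(),
            "year": truth["year"].to_numpy(),
        }
    )
    genotype_ids = sorted(set(truth["mother_genotype"]) | set(truth["donor_genotype"]))
    for gid in genotype_ids:
        panel.genotype(gid)  # parents must exist in the panel

    mom_codes = pd.Categorical(truth["mother_genotype"], categories=genotype_ids).codes
    dad_codes = pd.Categorical(truth["donor_genotype"], categories=genotype_ids).codes

    for marker in panel.markers:
        mid = marker.marker_id
        required = mid in panel.id_set
        parent_calls = []
        for gid in genotype_ids:
            call = panel.genotype(gid).call(mid)
            if call is None and required:
                raise DataError(
                    f"parent {gid} has no call at id-set marker {mid}"
                )
            parent_calls.append(call)
        if any(c is None for c in parent_calls):
            # marker unusable for any offspring of that parent: emit NA
            pass
        base_pairs = np.array(
            [c if c is not None else ("N", "N") for c in parent_calls]
        )
        mom_gamete = base_pairs[mom_codes, rng.integers(2, size=n)]
        dad_gamete = base_pairs[dad_codes, rng.integers(2, size=n)]

        if noise.error_rate > 0:
            err = rng.random(n) < noise.error_rate
            which = rng.integers(2, size=n)
            other = {marker.allele_pair[0]: marker.allele_pair[1],
                     marker.allele_pair[1]: marker.allele_pair[0],
                     "N": "N"}
            flip_mom = err & (which == 0)
            flip_dad = err & (which == 1)
            if flip_mom.any():
                mom_gamete = mom_gamete.copy()
                mom_gamete[flip_mom] = [other[b] for b in mom_gamete[flip_mom]]
            if flip_dad.any():
                dad_gamete = dad_gamete.copy()
                dad_gamete[flip_dad] = [other[b] for b in dad_gamete[flip_dad]]

        lo = np.where(mom_gamete <= dad_gamete, mom_gamete, dad_gamete)
        hi = np.where(mom_gamete <= dad_gamete, dad_gamete, mom_gamete)
        col = np.char.add(np.char.add(lo.astype("U1"), "/"), hi.astype("U1"))
        col = col.astype(object)
        col[(mom_gamete == "N") | (dad_gamete == "N")] = "NA"
        if noise.missing_rate > 0:
            col[rng.random(n) < noise.missing_rate] = "NA"
        calls[mid] = col
    return calls


# ---------------------------------------------------------------------------
# TSV I/O
# ---------------------------------------------------------------------------

def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_truth(path) -> pd.DataFrame:
    truth = pd.read_csv(path, sep="\t", dtype={"seed_id": str})
    missing = set(TRUTH_COLUMNS) - set(truth.columns)
    if missing:
        raise DataError(f"truth table lacks columns {sorted(missing)}")
    return truth


def write_calls(calls: pd.DataFrame, path) -> None:
    calls.to_csv(path, sep="\t", index=False, lineterminator="\n")


def read_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = set(CALL_META_COLUMNS) - set(calls.columns)
    if missing:
        raise DataError(f"calls table lacks columns {sorted(missing)}")
    calls["block"] = calls["block"].astype(int)
    calls["year"] = calls["year"].astype(int)
    if calls["seed_id"].duplicated().any():
        raise DataError("duplicate seed ids in calls table")
    return calls


def write_outputs(truth: pd.DataFrame, calls: pd.DataFrame, out_dir) -> dict:
    """Write truth and offspring-call tables; returns the file map."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"truth": out / "truth.tsv", "calls": out / "calls.tsv"}
    write_truth(truth, paths["truth"])
    write_calls(calls, paths["calls"])
    return paths
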