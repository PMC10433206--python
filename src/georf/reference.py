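"""Study-scale bookkeeping: feature-block and cohort arithmetic.

The national-scale study this package targets works with 1,784 ZIP-level
covariates (a 174-column climate block, 1,608 census-derived demographic
columns, and 2 vendor-rate columns) over a 405,540-patient case/control
cohort split at age 60.  These dataclasses make that arithmetic explicit
and checkable: block totals, stratum totals and pruning balances are
computed, never restated.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class FeatureBlockCounts:
    """Column bookkeeping of the assembled covariate table."""

    monthly_types: int = 12
    months: int = 12
    static_climate: int = 30
    acs_variables: int = 1606
    extra_demographic: int = 2  # population density, water/land ratio
    vendor: int = 2

    @property
    def monthly_climate(self) -> int:
        return self.monthly_types * self.months

    @property
    def climate_total(self) -> int:
        return self.monthly_climate + self.static_climate

    @property
    def demographic_total(self) -> int:
        return self.acs_variables + self.extra_demographic

    @property
    def total(self) -> int:
        return self.climate_total + self.demographic_total + self.vendor


@dataclass(frozen=True)
class PruningBalance:
    """Features in, features removed by correlation pruning."""

    n_input: int
    n_removed: int

    @property
    def n_retained(self) -> int:
        return self.n_input - self.n_removed


@dataclass(frozen=True)
class StratumCounts:
    """Case/control counts of one cohort stratum."""

    cases: int
    controls: int

    @property
    def total(self) -> int:
        return self.cases + self.controls

    @property
    def prevalence(self) -> float:
        return self.cases / self.total


#: Full study-scale cohort: overall and the two age strata.
STUDY_COHORT = StratumCounts(cases=14_131, controls=391_409)
STUDY_STRATUM_60_PLUS = StratumCounts(cases=4_231, controls=263_216)
STUDY_STRATUM_UNDER_60 = StratumCounts(cases=9_900, controls=128_193)

STUDY_FEATURES = FeatureBlockCounts()
STUDY_PRUNING = PruningBalance(n_input=STUDY_FEATURES.total, n_removed=248)


@dataclass(frozen=True)
class LoopScale:
    """Size of the all-against-all network stage at study scale."""

    n_features: int = STUDY_PRUNING.n_retained
    n_zip_samples: int = 31_378

    @property
    def candidate_edges(self) -> int:
        return self.n_features * (self.n_features - 1)

    def top_edges(self, fraction: float = 0.01) -> int:
        return int(fraction * self.candidate_edges)


STUDY_LOOP = LoopScale()
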