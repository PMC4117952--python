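"""Numeric parameters of the poly(A)-site pipeline.

Every tunable constant used downstream lives here so that a run can be
reproduced from its manifest.  The two bundled profiles correspond to the
two annotation regimes the pipeline was designed around: a sparsely
annotated genome (``mtr_like``: long 3'-UTR extensions, 200/400 nt) and a
well-annotated one (``ath_like``: 120/338 nt).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass


@dataclass(frozen=True)
class Parameters:
    """Pipeline constants (all lengths in nucleotides).

    Attributes
    ----------
    cluster_gap:
        Adjacent distinct cleavage positions closer than this chain into a
        single poly(A)-site cluster (PAC).
    internal_priming_a_run:
        Minimum run of consecutive genomic A immediately downstream of a
        cleavage site that marks a tag as an internal-priming artifact.
    internal_priming_window:
        Width of the downstream genomic window scanned for that A run.
    ext_with_utr / ext_without_utr:
        3' extension applied to genes with / without an annotated 3'-UTR.
    promoter_extent:
        Width of the promoter window upstream of the 5'-most transcribed
        coordinate.
    est_match_window:
        An EST-derived poly(A) site validates a PAC when a same-strand
        summit lies within this distance (inclusive).
    n_random_trials:
        Number of random gene draws in the conservation randomization test.
    profile_upstream / profile_downstream:
        Default window of the nucleotide-composition profiles around the
        cleavage site.
    nearby_antisense_distance:
        Maximum distance between an antisense PAC summit and the 3' end of
        a convergently transcribed neighbour for case-3 attribution.
    min_t_run:
        Minimum leading-T run for a raw read to count as a poly(T) tag.
    """

    cluster_gap: int = 24
    internal_priming_a_run: int = 6
    internal_priming_window: int = 10
    ext_with_utr: int = 200
    ext_without_utr: int = 400
    promoter_extent: int = 2000
    est_match_window: int = 50
    n_random_trials: int = 1000
    profile_upstream: int = 300
    profile_downstream: int = 100
    nearby_antisense_distance: int = 500
    min_t_run: int = 8

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not isinstance(v, int) or v <= 0:
                raise ValueError(f"Parameters.{f.name} must be a positive integer, got {v!r}")

    def replace(self, **kwargs) -> "Parameters":
        return dataclasses.replace(self, **kwargs)


#: Profile for a sparsely annotated genome (few annotated 3'-UTRs).
MTR_LIKE = Parameters(ext_with_utr=200, ext_without_utr=400)

#: Profile for a densely annotated genome.
ATH_LIKE = Parameters(ext_with_utr=120, ext_without_utr=338)

_PROFILES = {"mtr_like": MTR_LIKE, "ath_like": ATH_LIKE}


def species_profile(name: str, **overrides) -> Parameters:
    """Return a named parameter profile, optionally with field overrides."""
    if name == "custom":
        return Parameters(**overrides)
    try:
        base = _PROFILES[name]
    except KeyError:
        raise ValueError(f"unknown species profile {name!r}; expected one of "
                         f"{sorted(_PROFILES)} or 'custom'") from None
    return base.replace(**overrides) if overrides else base
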