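"""Channel metadata: anatomical regions, tissue classes and synthetic montage generation.

SEEG montages are sparse and clinically determined: a few tens of contacts
scattered over cortical gyri and deep structures (thalamus, amygdala,
hippocampus), with some contacts landing in white matter or visual cortex.
Downstream stages need per-channel anatomy to apply exclusion rules
(white matter, occipital) and to aggregate saliency by region, so the
montage generator emits a :class:`ChannelSpec` per contact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

#: Cortical gray-matter region codes (gyrus/lobule abbreviations).
CORTICAL_REGIONS = (
    "STG", "MTG", "ITG", "Precen", "Postcen", "INS", "FuG", "Pcun",
    "SMG", "Angular", "SFG", "MFG", "IFG", "SPL", "IPL", "CG",
)

#: Deep (subcortical) gray-matter structures reachable by depth electrodes.
SUBCORTICAL_REGIONS = ("Tha", "Amyg", "Hipp")

#: Classical speech/language network: removed wholesale in the
#: region-exclusion robustness analysis.
SPEECH_REGIONS = frozenset(
    {"Angular", "SFG", "MFG", "IFG", "STG", "MTG", "ITG", "Precen"}
)

#: Regions that are valid labels but never enter decoding models.
OCCIPITAL = "Occipital"
WHITE_MATTER = "WhiteMatter"

ALL_REGIONS = CORTICAL_REGIONS + SUBCORTICAL_REGIONS + (OCCIPITAL, WHITE_MATTER)


@dataclass(frozen=True)
class ChannelSpec:
    """Anatomical and simulation metadata for one recording contact.

    Parameters
    ----------
    name : str
        Unique channel label.
    region : str
        Region code from :data:`ALL_REGIONS`.
    domain : {"cortical", "subcortical", "none"}
        Anatomical domain; white matter contacts carry ``"none"``.
    tissue : {"gray", "white"}
        Tissue class at the contact.
    informative : bool
        Whether the simulator adds speech-state-dependent components
        to this channel.
    snr : float
        Dimensionless scale of the state-dependent components relative
        to the background noise standard deviation.
    """

    name: str
    region: str
    domain: str
    tissue: str
    informative: bool = False
    snr: float = 0.0

    def __post_init__(self) -> None:
        if self.region not in ALL_REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.domain not in ("cortical", "subcortical", "none"):
            raise ValueError(f"invalid domain {self.domain!r}")
        if self.tissue not in ("gray", "white"):
            raise ValueError(f"invalid tissue {self.tissue!r}")
        if self.region == WHITE_MATTER and (
            self.tissue != "white" or self.domain != "none"
        ):
            raise ValueError("white-matter channels must have tissue='white', domain='none'")
        if self.domain == "subcortical" and self.region not in SUBCORTICAL_REGIONS:
            raise ValueError(
                f"subcortical channels must lie in {SUBCORTICAL_REGIONS}, got {self.region!r}"
            )
        if self.informative and not self.snr > 0:
            raise ValueError("informative channels require snr > 0")


def region_domain(region: str) -> str:
    """Anatomical domain implied by a region code."""
    if region in SUBCORTICAL_REGIONS:
        return "subcortical"
    if region == WHITE_MATTER:
        return "none"
    return "cortical"


def make_channel_spec(name: str, region: str, informative: bool = False,
                      snr: float = 0.0) -> ChannelSpec:
    """Build a :class:`ChannelSpec` with domain/tissue inferred from the region."""
    return ChannelSpec(
        name=name,
        region=region,
        domain=region_domain(region),
        tissue="white" if region == WHITE_MATTER else "gray",
        informative=informative,
        snr=snr,
    )


def generate_channel_specs(
    n_channels: int,
    fraction_informative: float,
    region_pool: list[str] | tuple[str, ...] | None = None,
    seed: int = 0,
    snr: float = 1.0,
    informative_regions: list[str] | None = None,
    name_prefix: str = "ch",
) -> list[ChannelSpec]:
    """Draw a synthetic montage of ``n_channels`` contacts.

    ``round(n_channels * fraction_informative)`` channels are marked
    informative with effect scale ``snr``; the rest are pure background.
    Informative regions alternate between cortical and subcortical codes
    when both are present in the pool, so state information is spread
    across both anatomical domains. With the default pool and
    ``n_channels >= 10`` one occipital and one white-matter contact are
    always included so the exclusion rules have something to act on.

    Parameters
    ----------
    informative_regions : list of str, optional
        Exact region codes to cycle through for the informative
        channels (overrides the alternating default); used e.g. to
        place a fixed number of informative contacts inside and outside
        the classical speech-region set.
    """
    if n_channels < 1:
        raise ValueError("n_channels must be >= 1")
    if not 0.0 <= fraction_informative <= 1.0:
        raise ValueError("fraction_informative must lie in [0, 1]")
    default_pool = region_pool is None
    pool = list(region_pool) if region_pool is not None else list(
        CORTICAL_REGIONS + SUBCORTICAL_REGIONS
    )
    if not pool:
        raise ValueError("region pool is empty")
    for r in pool:
        if r not in ALL_REGIONS:
            raise ValueError(f"unknown region {r!r} in pool")

    rng = np.random.default_rng(seed)
    n_informative = int(round(n_channels * fraction_informative))
    if n_informative > 0 and not snr > 0:
        raise ValueError("snr must be > 0 when informative channels are requested")

    # Region sequence for informative contacts: alternate domains when possible.
    if informative_regions is not None:
        inf_cycle = list(informative_regions)
        if not inf_cycle:
            raise ValueError("informative_regions is empty")
    else:
        cort = [r for r in pool if region_domain(r) == "cortical" and r != OCCIPITAL]
        sub = [r for r in pool if region_domain(r) == "subcortical"]
        rng.shuffle(cort)
        rng.shuffle(sub)
        if cort and sub:
            inf_cycle = [x for pair in zip(cort, sub) for x in pair]
            inf_cycle += cort[len(sub):] + sub[len(cort):]
        else:
            inf_cycle = cort or sub
        if not inf_cycle and n_informative > 0:
            raise ValueError("pool contains no gray-matter regions for informative channels")

    specs: list[ChannelSpec] = []
    for i in range(n_informative):
        region = inf_cycle[i % len(inf_cycle)]
        specs.append(make_channel_spec(f"{name_prefix}{i:03d}", region, True, snr))

    n_background = n_channels - n_informative
    forced: list[str] = []
    if default_pool and n_channels >= 10 and n_background >= 2:
        forced = [OCCIPITAL, WHITE_MATTER]
    bg_choices = [r for r in pool if r != WHITE_MATTER]
    for j in range(n_background):
        region = forced[j] if j < len(forced) else bg_choices[
            rng.integers(len(bg_choices))
        ]
        specs.append(
            make_channel_spec(f"{name_prefix}{n_informative + j:03d}", region)
        )
    return specs
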