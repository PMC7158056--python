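"""Study-condition pools and specificity weights for the in-silico swap.

Two emulated strains drive the oleA-exchange experiment:

* a Micrococcus-luteus-like host — anteiso-dominated C13–C17 fatty-acyl
  pool with no straight-chain species, and an OleA strongly preferring
  anteiso-C15, so the native olefin profile peaks at C29 aiai;
* a Kocuria-like donor — a shorter, iso/straight-rich pool and an OleA
  preferring iso-C13 and straight chains, giving C23–C25 olefins with
  iso-branched and straight-chain ends.

These are fixed model conditions, not free parameters: abundances follow
the common C14–C17, anteiso-and-saturated-dominated fatty-acid spectrum
of Micrococcales, with the Kocuria pool shifted shorter and toward
iso/straight chains as its olefin products require.
"""

from __future__ import annotations

from .condensation import FattySpecies, SpecificityWeights


def host_pool() -> list[FattySpecies]:
    """M.-luteus-like precursor pool; note: no straight-chain species."""
    return [
        FattySpecies(15, "anteiso", 0.55),
        FattySpecies(17, "anteiso", 0.12),
        FattySpecies(14, "anteiso", 0.08),
        FattySpecies(15, "iso", 0.12),
        FattySpecies(13, "iso", 0.13),
    ]


def host_weights() -> SpecificityWeights:
    """Host OleA: strong preference for anteiso-C15 (modal product C29 aiai)."""
    return SpecificityWeights(
        {
            (15, "anteiso"): 2.0,
            (17, "anteiso"): 0.5,
            (14, "anteiso"): 0.3,
            (15, "iso"): 0.3,
            (13, "iso"): 0.2,
        }
    ).anchored(host_pool())


def donor_pool() -> list[FattySpecies]:
    """Kocuria-like pool: shorter chains, substantial iso and straight species.

    Covers every host-pool species (at low abundance) so that weights
    fitted on this pool are defined for the host pool too.
    """
    return [
        FattySpecies(13, "iso", 0.30),
        FattySpecies(12, "straight", 0.14),
        FattySpecies(13, "straight", 0.10),
        FattySpecies(14, "iso", 0.12),
        FattySpecies(15, "anteiso", 0.16),
        FattySpecies(17, "anteiso", 0.06),
        FattySpecies(14, "anteiso", 0.05),
        FattySpecies(15, "iso", 0.07),
    ]


def donor_weights_true() -> SpecificityWeights:
    """Donor OleA: prefers iso-C13 and straight chains (modal product C25)."""
    return SpecificityWeights(
        {
            (13, "iso"): 3.5,
            (12, "straight"): 1.2,
            (13, "straight"): 1.0,
            (14, "iso"): 0.8,
            (15, "anteiso"): 0.15,
            (17, "anteiso"): 0.1,
            (14, "anteiso"): 0.15,
            (15, "iso"): 0.3,
        }
    ).anchored(donor_pool())


def recovery_pool() -> list[FattySpecies]:
    """12-species pool (4 chain lengths x 3 branches) for parameter recovery."""
    species = []
    base = {13: 0.30, 14: 0.15, 15: 0.40, 16: 0.15}
    branch_share = {"iso": 0.35, "anteiso": 0.45, "straight": 0.20}
    for chain, f_chain in base.items():
        for branch, f_branch in branch_share.items():
            species.append(FattySpecies(chain, branch, f_chain * f_branch))
    return species


def recovery_weights() -> SpecificityWeights:
    """Ground-truth weights for the recovery benchmark: smooth 6-fold spread."""
    w = {}
    for i, s in enumerate(recovery_pool()):
        w[s.key] = 0.5 + 0.25 * i  # 0.5 .. 3.25
    return SpecificityWeights(w).anchored(recovery_pool())
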