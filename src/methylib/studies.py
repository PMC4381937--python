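"""Frozen synthetic study conditions used by the analyses and tests.

Each function returns the genome specification (and companion parameters)
for one of the three synthetic experiments the package is exercised on.
Centralising them keeps the analysis scripts, the test suite and the
reproduction script on identical conditions.
"""

from __future__ import annotations

from .synthetic import SyntheticGenomeSpec

#: Collection windows scanned when locating the optimal DNase window (bp).
SCAN_WINDOWS = (100, 200, 300, 600, 1000)

#: Size-selection bounds applied to digested libraries (bp).
SIZE_RANGE = (100, 600)


def prokaryotic_library_conditions(seed: int = 0) -> SyntheticGenomeSpec:
    """TF-free genome emulating the prokaryotic fragment library.

    No TF sites, so CG density is the only methylation determinant; long
    islands spanning the full density range of interest give digested
    fragments across the sigmoid's dynamic range.
    """
    return SyntheticGenomeSpec(
        n_contigs=3,
        contig_length=60_000,
        n_islands=12,
        island_length_range=(1200, 2500),
        island_density_range=(3.0, 20.0),
        background_density=1.5,
        n_tf_sites=0,
        seed=seed,
    )


def window_scan_conditions(seed: int = 0) -> SyntheticGenomeSpec:
    """Isolated-TF-effect genome for the DNase collection-window scan.

    Density is uniform (no islands) so that TF binding is the only source
    of methylation variance; many sites give the scan statistical power.
    """
    return SyntheticGenomeSpec(
        n_contigs=4,
        contig_length=50_000,
        n_islands=0,
        background_density=2.0,
        n_tf_sites=40,
        seed=seed,
    )


def dynamics_conditions(seed: int = 0) -> SyntheticGenomeSpec:
    """Island genome with dense TF binding for condition-pair dynamics.

    Sites are frequent enough that factor loss changes a few percent of
    the CGs in every prediction bin, which an upper-percentile change
    profile can resolve.
    """
    return SyntheticGenomeSpec(
        n_contigs=3,
        contig_length=60_000,
        n_islands=10,
        n_tf_sites=60,
        seed=seed,
    )
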