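"""Shared naming for the 10 well-level morphology parameters.

The screen summarises each well into ten image-derived measures covering
neuronal survival (nuclear block), dendritic arborisation (dendritic block)
and synaptic connectivity (puncta densities plus staining intensities).
Downstream statistics refer to parameters by these column names.
"""

from __future__ import annotations

#: 10 core morphology parameters, in canonical column order.
PARAMETERS: tuple[str, ...] = (
    "nuclei_count",
    "neuron_count",
    "primary_neurites_per_neuron",
    "branch_points_per_neuron",
    "dendrite_length_per_neuron",
    "presynaptic_puncta_density",
    "presynaptic_intensity",
    "postsynaptic_puncta_density",
    "postsynaptic_intensity",
    "colocalized_puncta_density",
)

#: Correlation blocks used by the generator and reported by QC.
NUCLEAR_BLOCK = ("nuclei_count", "neuron_count")
DENDRITIC_BLOCK = (
    "primary_neurites_per_neuron",
    "branch_points_per_neuron",
    "dendrite_length_per_neuron",
)
SYNAPTIC_COUNT_BLOCK = (
    "presynaptic_puncta_density",
    "postsynaptic_puncta_density",
    "colocalized_puncta_density",
)
SYNAPTIC_INTENSITY_BLOCK = ("presynaptic_intensity", "postsynaptic_intensity")

#: Four representative core parameters used for phenotypic clustering.
REPRESENTATIVE_PARAMETERS: tuple[str, ...] = (
    "neuron_count",
    "dendrite_length_per_neuron",
    "presynaptic_puncta_density",
    "postsynaptic_puncta_density",
)

#: Well annotation columns preceding the parameter columns in a well table.
WELL_KEY_COLUMNS: tuple[str, ...] = (
    "batch",
    "plate",
    "well",
    "is_edge",
    "div",
    "shrna_id",
    "gene",
    "treatment_class",
)

TREATMENT_SCRAMBLED = "scrambled"
TREATMENT_EXPERIMENTAL = "experimental"
TREATMENT_UNTREATED = "untreated"
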