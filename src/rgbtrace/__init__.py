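"""rgbtrace: quantitative analysis of RGB multicolour clonal cell marking.

Cells co-transduced with red, green and blue marker vectors acquire a
combinatorial colour — one of seven classes (R, G, B, RG, GB, RB, RGB) —
whose population distribution is fixed by the per-vector transduction
rate, and a hue that acts as a clonal watermark.  This package provides
the analytic co-transduction model and its inverse (rate inference from
class counts), ground-truthed synthetic populations and scenes, per-cell
intensity quantification, the brightness/threshold colour-calling
procedure, hue-based clonal grouping, and neuron morphometry (Sholl
profiles, spine density, bouton size classes).
"""

__version__ = "0.1.0"

from .model import (
    ALL_CLASSES,
    CLASS_PATTERNS,
    LABELLED_CLASSES,
    ClassDistribution,
    FitResult,
    GofResult,
    VectorSet,
    class_curves,
    class_of_pattern,
    expected_class_distribution,
    fit_transduction_rate,
    goodness_of_fit,
    moi_from_probability,
    simulate_class_counts,
    titre_from_dilution,
    transduction_probability,
)
from .synth import (
    CellRecord,
    NoiseModel,
    SyntheticScene,
    generate_clones,
    generate_neuron_tree,
    generate_population,
    population_table,
    render_scene,
)
from .quantify import (
    exclude_ambiguous,
    match_labels,
    measure_cells,
    rescale_to_8bit,
    segment_simple,
)
from .classify import (
    BRIGHTNESS_WEIGHTS,
    ColorCall,
    class_distribution,
    classify_cell,
    classify_table,
    cluster_by_hue,
    hue_saturation,
    perceived_brightness,
    scatter3d_export,
)
from .morphometry import (
    NeuronTree,
    ShollProfile,
    SwcNode,
    bouton_size_histogram,
    compare_profiles,
    sholl,
    sholl_radii,
    spine_density,
)
from .pipeline import PipelineError, RunConfig, preset_config, run_pipeline

__all__ = [
    "ALL_CLASSES", "CLASS_PATTERNS", "LABELLED_CLASSES",
    "BRIGHTNESS_WEIGHTS",
    "CellRecord", "ClassDistribution", "ColorCall", "FitResult", "GofResult",
    "NeuronTree", "NoiseModel", "PipelineError", "RunConfig", "ShollProfile",
    "SwcNode", "SyntheticScene", "VectorSet",
    "bouton_size_histogram", "class_curves", "class_distribution",
    "class_of_pattern", "classify_cell", "classify_table", "cluster_by_hue",
    "compare_profiles", "exclude_ambiguous", "expected_class_distribution",
    "fit_transduction_rate", "generate_clones", "generate_neuron_tree",
    "generate_population", "goodness_of_fit", "hue_saturation",
    "match_labels", "measure_cells", "moi_from_probability",
    "perceived_brightness", "population_table", "preset_config",
    "render_scene", "rescale_to_8bit", "run_pipeline", "scatter3d_export",
    "segment_simple", "sholl", "sholl_radii", "simulate_class_counts",
    "spine_density", "titre_from_dilution", "transduction_probability",
]
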