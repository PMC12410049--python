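import pytest

from origamod.geometry import StructureKind, TargetStructure
from origamod.builder import build_design

BUILD_SEED = 11


@pytest.fixture(scope="session")
def all_recipe_bundles():
    """One built bundle per demonstrated assembly recipe."""
    targets = {
        "continuous_tiling": TargetStructure(StructureKind.CONTINUOUS_TILING),
        "tetramer_tiling": TargetStructure(StructureKind.TETRAMER_TILING),
        "shell_T1": TargetStructure(StructureKind.SHELL, T=1),
        "shell_T4": TargetStructure(StructureKind.SHELL, T=4),
        "tube_m6": TargetStructure(StructureKind.TUBE, m=6),
    }
    return {name: build_design(t, seed=BUILD_SEED) for name, t in targets.items()}


@pytest.fixture(scope="session")
def t4_bundle(all_recipe_bundles):
    return all_recipe_bundles["shell_T4"]
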