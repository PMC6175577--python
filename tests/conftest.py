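import pytest

from brctscan.motif import PhosphoWindow, builtin_patterns
from brctscan.scan import SequenceRecord
from brctscan.synthetic import RAD9_TAIL


def make_window(
    minus5: str = "V",
    minus4: str = "L",
    minus3: str = "A",
    minus2: str = "E",
    minus1: str = "D",
    phospho: str = "S",
    plus1: str = "E",
    minus6: str = "P",
    plus2: str = "G",
    context_mode: str = "short",
) -> PhosphoWindow:
    """Window builder defaulting to the RAD9 tail context (...PVLAED-pS-EG)."""
    return PhosphoWindow(
        {
            -6: minus6, -5: minus5, -4: minus4, -3: minus3, -2: minus2,
            -1: minus1, 0: phospho, 1: plus1, 2: plus2,
        },
        context_mode=context_mode,
    )


@pytest.fixture(scope="session")
def patterns():
    return builtin_patterns()


@pytest.fixture()
def rad9_tail_record():
    """C-terminal 45 residues of human RAD9 (347-391), S387 at position 41."""
    return SequenceRecord(id="RAD9", description="tail", residues=RAD9_TAIL)
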