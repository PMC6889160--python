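import numpy as np
import pytest

from methsector.ingest import SequencedFragment, Window
from methsector.matrix import ReadMethylationMatrix


@pytest.fixture
def window3():
    """A 100-bp window with three CpGs."""
    return Window("chr1", 0, 100, (12, 48, 90))


def make_matrix(window, rows, conditions):
    """Build a ReadMethylationMatrix from a list of pattern tuples."""
    m = len(rows)
    values = (
        np.array(rows, dtype=np.uint8)
        if m
        else np.empty((0, window.n_cpgs), dtype=np.uint8)
    )
    return ReadMethylationMatrix(
        window,
        [f"r{i}" for i in range(m)],
        np.array(list(conditions), dtype=object),
        values,
    )


def fragment(fid, condition, chrom, calls):
    return SequencedFragment(fid, condition, chrom, dict(calls))


@pytest.fixture
def matrix_factory(window3):
    def _make(rows, conditions=None):
        conds = conditions if conditions is not None else ["A"] * len(rows)
        return make_matrix(window3, rows, conds)

    return _make


def write_sam(path, records, chrom="chr1", length=1000):
    """Write a minimal plain-text SAM file with the given record lines."""
    lines = ["@HD\tVN:1.6\tSO:coordinate", f"@SQ\tSN:{chrom}\tLN:{length}"]
    lines.extend(records)
    path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    return path
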