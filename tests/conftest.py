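import pytest

from exomet.dom import packaged_dom_set
from exomet.metabolites import load_function_vocabulary, load_metabolite_db


@pytest.fixture(scope="session")
def db():
    """The packaged annotated-metabolite table (43 records)."""
    return load_metabolite_db()


@pytest.fixture(scope="session")
def vocabulary():
    return load_function_vocabulary()


@pytest.fixture(scope="session")
def dom_sets():
    return {name: packaged_dom_set(name) for name in ("mesocosm", "north_sea")}


@pytest.fixture
def write_peaklist(tmp_path):
    """Write a small delimited peak list and return its path."""

    def _write(rows, name="peaks.tsv", header="mz\tintensity\tsnr", sep="\t"):
        lines = [header]
        for row in rows:
            lines.append(sep.join(str(v) for v in row))
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
        return path

    return _write
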