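import numpy as np
import pytest

from xlmap.crosslink_io import CrossLink, PPI, make_link
from xlmap.distance import DistanceRecord, OVER_LENGTH, PairReport, SATISFIED
from xlmap.structure_io import ChainRecord, ResidueRecord, StructureModel


def build_structure(entry_id: str, chains: dict[str, tuple[str, np.ndarray]],
                    ) -> StructureModel:
    """In-memory StructureModel from {chain_id: (sequence, (L,3) coords)}.

    A None row in the coordinate array marks a residue without a Cα.
    """
    chain_records = []
    for cid in sorted(chains):
        seq, coords = chains[cid]
        residues = []
        for i, aa in enumerate(seq):
            xyz = coords[i]
            residues.append(ResidueRecord(
                auth_seq_num=i + 1,
                insertion_code="",
                aa=aa,
                ca_xyz=None if xyz is None else np.asarray(xyz, dtype=float),
            ))
        chain_records.append(ChainRecord(cid, residues))
    return StructureModel(entry_id=entry_id, chains=chain_records)


def fake_report(mapped: list[tuple[float, float]], n_unmapped: int = 0,
                entry_id: str = "1abc") -> PairReport:
    """PairReport from a list of (distance, linker_max) mapped records."""
    links = [make_link("P1", i + 1, "P2", i + 1, "DSS")
             for i in range(len(mapped) + n_unmapped)]
    records = []
    for link, (d, dmax) in zip(links, mapped):
        status = SATISFIED if d <= dmax else OVER_LENGTH
        res = ResidueRecord(link.pos_a, "", "K", np.zeros(3))
        records.append(DistanceRecord(link, entry_id, "A", "B", res, res,
                                      d, status, dmax))
    for link in links[len(mapped):]:
        records.append(DistanceRecord(link, entry_id, None, None, None, None,
                                      None, "unmapped", 30.0))
    ppi = PPI("P1", "P2", tuple(links))
    n_sat = sum(1 for r in records if r.status == SATISFIED)
    n_over = sum(1 for r in records if r.status == OVER_LENGTH)
    return PairReport(ppi, entry_id, records, len(links), n_sat + n_over,
                      n_sat, n_over)


@pytest.fixture(scope="session")
def demo_run(tmp_path_factory):
    """One demo scene executed through the full pipeline, shared per session."""
    from xlmap.cli import RunConfig, run_pipeline
    from xlmap.fixtures import write_demo

    root = tmp_path_factory.mktemp("demo")
    config_path = write_demo(root, seed=7)
    config = RunConfig.from_yaml(config_path)
    outputs = run_pipeline(config)
    return config, outputs


def random_rotation(rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """A uniform-ish proper rotation matrix plus a random translation."""
    q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
    if np.linalg.det(q) < 0:
        q[:, 0] = -q[:, 0]
    return q, rng.uniform(-50, 50, size=3)
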