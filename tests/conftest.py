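import pytest

from barcodiv.barcode_io import BarcodeDataset, BarcodeRecord


def make_record(rid, seq, species="Melitaea athalia", family="Nymphalidae",
                lat=None, lon=None):
    return BarcodeRecord(record_id=rid, species=species, family=family,
                         sequence=seq, latitude=lat, longitude=lon)


def make_dataset(seqs, species=None, length=None, coords=None):
    """Toy dataset from {id: sequence}; optional {id: species}, {id: (lat, lon)}."""
    length = length or max(len(s) for s in seqs.values())
    records = []
    for rid, seq in seqs.items():
        lat, lon = (coords or {}).get(rid, (None, None))
        records.append(make_record(
            rid, seq,
            species=(species or {}).get(rid, "Melitaea athalia"),
            lat=lat, lon=lon))
    return BarcodeDataset(records, alignment_length=length)


@pytest.fixture
def four_taxon_additive():
    """Additive distances from ((A:1,B:2):1,(C:3,D:4)) with internal edge 1."""
    import numpy as np
    from barcodiv.haplotypes import DistanceMatrix
    labels = ["A", "B", "C", "D"]
    d = np.array([
        [0, 3, 5, 6],
        [3, 0, 6, 7],
        [5, 6, 0, 7],
        [6, 7, 7, 0],
    ], dtype=float)
    return DistanceMatrix(labels, d)
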