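import pytest

from ustrina.deposit import Deposit, FragmentRecord, SquareID, StratumID


def lot(square: str, weight: float, size_class: str = "lt20",
        region: str = "undetermined", us: int = 11, cut=None) -> FragmentRecord:
    return FragmentRecord(
        square=SquareID.from_label(square),
        stratum=StratumID(us, cut),
        size_class=size_class,
        region=region,
        weight=weight,
    )


@pytest.fixture
def small_deposit() -> Deposit:
    """A hand-built deposit: a two-square core on G4/G5 plus two outliers.

    Totals: lt20 = 700 g, ge20 = 260 g (cranial 60 g, postcranial 180 g,
    undetermined 20 g), tooth = 8 g; grand total 968 g, of which 948 g in
    US 11 and 20 g in US 12.
    """
    records = [
        lot("G4", 400.0),
        lot("G4", 100.0, "ge20", "postcranial"),
        lot("G4", 40.0, "ge20", "cranial"),
        lot("G4", 5.0, "tooth", "tooth"),
        lot("G5", 250.0, cut="I"),
        lot("G5", 80.0, "ge20", "postcranial", cut="I"),
        lot("G5", 20.0, "ge20", "cranial", cut="roof"),
        lot("G5", 3.0, "tooth", "tooth"),
        lot("A26", 30.0),
        lot("A26", 20.0, "ge20", "undetermined"),
        lot("C19", 20.0, us=12),
    ]
    return Deposit(records)
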