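"""The 29-label tag set for PHI de-identification.

Protected health information (PHI) categories follow the i2b2 2014
de-identification challenge definitions: wherever a general class has
subclasses, only the subclasses are used as token labels; subclass-free
classes (profession, age, date) label tokens directly.  A single ``non-PHI``
label marks everything else, giving 28 PHI labels + 1 = 29 in total.

Five identifier subclasses (IP address, social security number, account
number, license number, vehicle identification) are defined in the scheme
but were absent from the published challenge data; :data:`ABSENT_LABELS`
records them so corpus generators can restrict themselves to the 23
classes that actually occur.
"""

from __future__ import annotations

from dataclasses import dataclass, field

NON_PHI = "non-PHI"

# PHI labels in category order: Name, Profession, Location, Age, Date,
# Contact, Identification.
PHI_LABELS: tuple[str, ...] = (
    # Name subclasses
    "patient",
    "clinician",
    "username",
    # Profession (no subclasses)
    "profession",
    # Location subclasses
    "hospital",
    "organization",
    "street",
    "city",
    "state",
    "country",
    "zip",
    "location-other",
    # Age (no subclasses)
    "age",
    # Date (no subclasses)
    "date",
    # Contact subclasses
    "phone",
    "fax",
    "email",
    "url",
    "ip-address",
    # Identification subclasses
    "social-security-number",
    "medical-record-number",
    "health-plan-number",
    "account-number",
    "license-number",
    "vehicle-id",
    "device-id",
    "biometric-id",
    "id-number",
)

#: PHI subclasses not present in the published challenge corpus.
ABSENT_LABELS: frozenset[str] = frozenset(
    {
        "ip-address",
        "social-security-number",
        "account-number",
        "license-number",
        "vehicle-id",
    }
)

#: The 23 PHI labels that occur in the published corpus.
PRESENT_PHI_LABELS: tuple[str, ...] = tuple(
    lab for lab in PHI_LABELS if lab not in ABSENT_LABELS
)


@dataclass(frozen=True)
class LabelScheme:
    """Ordered label set with index lookup and PHI/non-PHI membership."""

    labels: tuple[str, ...]
    index: dict[str, int] = field(repr=False)

    def __len__(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        try:
            return self.index[label]
        except KeyError:
            raise KeyError(f"unknown label: {label!r}") from None

    def is_phi(self, label: str) -> bool:
        self.index_of(label)  # validate
        return label != NON_PHI

    def __contains__(self, label: str) -> bool:
        return label in self.index


def build_label_scheme() -> LabelScheme:
    """Return the 29-label scheme (28 PHI subclasses/classes + non-PHI)."""
    labels = PHI_LABELS + (NON_PHI,)
    return LabelScheme(labels=labels, index={lab: i for i, lab in enumerate(labels)})
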