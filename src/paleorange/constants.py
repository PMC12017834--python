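"""Physical constants shared across the geochronology and isotope modules.

Decay constants follow the modern consensus half-lives; Sr/Rb/Kr isotope
masses and natural abundance ratios are from standard tables. All constants
are module-level defaults and can be overridden through the dataclasses that
consume them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = ["DecayConstants", "IsotopeConstants", "DECAY", "SR_CONSTANTS"]


@dataclass(frozen=True)
class DecayConstants:
    """U- and Th-series decay constants in 1/year.

    Defaults correspond to half-lives of 4.4683 Gyr (238U), 245.62 kyr
    (234U), 75.584 kyr (230Th) and 14.05 Gyr (232Th).
    """

    lambda_238: float = math.log(2.0) / 4.4683e9
    lambda_234: float = math.log(2.0) / 245_620.0
    lambda_230: float = math.log(2.0) / 75_584.0
    lambda_232: float = math.log(2.0) / 1.405e10

    def __post_init__(self) -> None:
        if not (self.lambda_230 > self.lambda_234 > self.lambda_238 > 0):
            raise ValueError("decay constants must satisfy λ230 > λ234 > λ238 > 0")


DECAY = DecayConstants()


@dataclass(frozen=True)
class IsotopeConstants:
    """Constants for LA-MC-ICP-MS Sr isotope data reduction.

    ``r88_86_canonical`` is the canonical 88Sr/86Sr used for the exponential
    mass-bias law (86Sr/88Sr = 0.1194). Kr and Rb ratios are natural
    abundance ratios used to strip isobaric interferences at masses 84, 86
    and 87 from the monitor beams at masses 82 (Kr) and 85 (Rb).
    """

    r88_86_canonical: float = 8.375209
    # natural Kr abundances: 82Kr 11.59%, 83Kr 11.50%, 84Kr 56.99%, 86Kr 17.28%
    kr84_82: float = 56.99 / 11.59
    kr86_82: float = 17.28 / 11.59
    kr84_83: float = 56.99 / 11.50
    kr86_83: float = 17.28 / 11.50
    # natural 87Rb/85Rb (27.83% / 72.17%)
    rb87_85: float = 27.83 / 72.17
    # natural 84Sr/86Sr, used as a post-correction quality flag
    r84_86_natural: float = 0.0565
    # exact isotope masses (u)
    m_sr84: float = 83.913419
    m_sr86: float = 85.909261
    m_sr87: float = 86.908878
    m_sr88: float = 87.905613
    m_rb85: float = 84.911790
    m_rb87: float = 86.909180
    m_kr82: float = 81.913481
    m_kr83: float = 82.914127
    m_kr84: float = 83.911507
    m_kr86: float = 85.910610
    # accepted modern seawater 87Sr/86Sr used for bracketing normalisation
    seawater_87_86: float = 0.709182


SR_CONSTANTS = IsotopeConstants()
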