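{
 "universe": "A00-Y98",
 "unmapped": [
  "A10",
  "A11",
  "A12",
  "A13",
  "A14",
  "A17",
  "A18",
  "A19",
  "C27",
  "C28",
  "C29",
  "C59",
  "D49",
  "D90",
  "D91",
  "D92",
  "D93",
  "D94",
  "D95",
  "D96",
  "D97",
  "D98",
  "D99",
  "E08",
  "E09",
  "E36",
  "E37",
  "E38",
  "E39",
  "E47",
  "E48",
  "E49",
  "E91",
  "E92",
  "E93",
  "E94",
  "E95",
  "E96",
  "E97",
  "E98",
  "E99",
  "G06",
  "G07",
  "G08",
  "G09",
  "G38",
  "G39",
  "G42",
  "G43",
  "G44",
  "G45",
  "G46",
  "G47",
  "G48",
  "G49",
  "H96",
  "H97",
  "H98",
  "H99",
  "I00",
  "I01",
  "I02",
  "I03",
  "I04",
  "I05",
  "I06",
  "I07",
  "I08",
  "I09",
  "I16",
  "I17",
  "I18",
  "I19",
  "I53",
  "I54",
  "I55",
  "I56",
  "I57",
  "I58",
  "I59",
  "J23",
  "J24",
  "J25",
  "J26",
  "J27",
  "J28",
  "J29",
  "K32",
  "K33",
  "K34",
  "K35",
  "K36",
  "K37",
  "K38",
  "K39",
  "K94",
  "K95",
  "K96",
  "K97",
  "K98",
  "K99",
  "O09",
  "O17",
  "O18",
  "O19",
  "P16",
  "P17",
  "P18",
  "P19",
  "P97",
  "P98",
  "P99",
  "R70",
  "R71",
  "R72",
  "R73",
  "R74",
  "R75",
  "R76",
  "R77",
  "R78",
  "R79",
  "R80",
  "R81",
  "R82",
  "R83",
  "R84",
  "R85",
  "R86",
  "R87",
  "R88",
  "R89",
  "R90",
  "R91",
  "R92",
  "R93",
  "R94",
  "R95",
  "R96",
  "R97",
  "R98",
  "U00",
  "U01",
  "U02",
  "U03",
  "U04",
  "U05",
  "U06",
  "U07",
  "U08",
  "U09",
  "U10",
  "U11",
  "U12",
  "U13",
  "U14",
  "U15",
  "U16",
  "U17",
  "U18",
  "U19",
  "U20",
  "U21",
  "U22",
  "U23",
  "U24",
  "U25",
  "U26",
  "U27",
  "U28",
  "U29",
  "U30",
  "U31",
  "U32",
  "U33",
  "U34",
  "U35",
  "U36",
  "U37",
  "U38",
  "U39",
  "U40",
  "U41",
  "U42",
  "U43",
  "U44",
  "U45",
  "U46",
  "U47",
  "U48",
  "U49",
  "U50",
  "U51",
  "U52",
  "U53",
  "U54",
  "U55",
  "U56",
  "U57",
  "U58",
  "U59",
  "U60",
  "U61",
  "U62",
  "U63",
  "U64",
  "U65",
  "U66",
  "U67",
  "U68",
  "U69",
  "U70",
  "U71",
  "U72",
  "U73",
  "U74",
  "U75",
  "U76",
  "U77",
  "U78",
  "U79",
  "U80",
  "U81",
  "U82",
  "U83",
  "U84",
  "U85",
  "U86",
  "U87",
  "U88",
  "U89",
  "U90",
  "U91",
  "U92",
  "U93",
  "U94",
  "U95",
  "U96",
  "U97",
  "U98",
  "U99",
  "V00"
 ],
 "conflicts": [
  {
   "code": "P95",
   "va_codes": [
    "VAs-11.01",
    "VAs-11.02"
   ]
  }
 ]
}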