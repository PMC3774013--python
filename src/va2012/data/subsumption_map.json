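{
  "entries": [
    {"cause_2007": "Other digestive disease", "target_va_code": "VAs-98"},
    {"cause_2007": "Typhoid and paratyphoid", "target_va_code": "VAs-01.99"},
    {"cause_2007": "Viral hepatitis", "target_va_code": "VAs-01.99"},
    {"cause_2007": "Leishmaniasis", "target_va_code": "VAs-01.99"},
    {"cause_2007": "Malignant melanoma of skin", "target_va_code": "VAs-02.99"},
    {"cause_2007": "Malignant neoplasm of lymphoid, haematopoietic and related tissue", "target_va_code": "VAs-02.99"},
    {"cause_2007": "Other specified neoplasms", "target_va_code": "VAs-02.99"},
    {"cause_2007": "Other specified endocrine disorders", "target_va_code": "VAs-98"},
    {"cause_2007": "Endocrine disorders, unspecified", "target_va_code": "VAs-98"},
    {"cause_2007": "Other specified diseases of the respiratory system", "target_va_code": "VAs-98"},
    {"cause_2007": "Respiratory disorder, unspecified", "target_va_code": "VAs-98"},
    {"cause_2007": "Respiratory failure, not elsewhere classified", "target_va_code": "VAs-98"},
    {"cause_2007": "Other diseases of intestine", "target_va_code": "VAs-98"},
    {"cause_2007": "Disease of intestine, unspecified", "target_va_code": "VAs-98"},
    {"cause_2007": "Specified mental disorders", "target_va_code": "VAs-98"},
    {"cause_2007": "Mental disorders, unspecified", "target_va_code": "VAs-98"},
    {"cause_2007": "Other specified disorders of the nervous system", "target_va_code": "VAs-98"},
    {"cause_2007": "Nervous system disorders, not otherwise classified", "target_va_code": "VAs-98"},
    {"cause_2007": "Alzheimer's disease", "target_va_code": "VAs-98"},
    {"cause_2007": "Other specified direct maternal causes", "target_va_code": "VAs-09.99"},
    {"cause_2007": "Congenital viral diseases", "target_va_code": "VAs-01.99"},
    {"cause_2007": "Congenital malformations of the nervous system", "target_va_code": "VAs-10.06"},
    {"cause_2007": "Other specified disorders related to perinatal period", "target_va_code": "VAs-10.99"},
    {"cause_2007": "Lack of food and/or water", "target_va_code": "VAs-12.99"},
    {"cause_2007": "Legal intervention", "target_va_code": "VAs-12.99"},
    {"cause_2007": "Accident, unspecified", "target_va_code": "VAs-12.99"},
    {"cause_2007": "Other specified event, undetermined intent", "target_va_code": "VAs-12.99"}
  ]
}
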