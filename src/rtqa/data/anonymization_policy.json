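{
  "version": "rtqa default de-identification policy v1 (HIPAA Safe-Harbor identifier categories)",
  "identity_actions": {
    "patient_name": "REMOVE",
    "patient_mrn": "HASH_PSEUDONYM",
    "birth_date": "REMOVE",
    "address": "REMOVE",
    "phone": "REMOVE",
    "sex": "KEEP"
  },
  "dicom_actions": {
    "PatientName": "REPLACE_DUMMY",
    "PatientID": "HASH_PSEUDONYM",
    "PatientBirthDate": "REMOVE",
    "PatientSex": "KEEP",
    "OtherPatientIDs": "REMOVE",
    "InstitutionName": "REMOVE",
    "InstitutionAddress": "REMOVE",
    "ReferringPhysicianName": "REMOVE",
    "OperatorsName": "REMOVE",
    "AccessionNumber": "REMOVE",
    "StudyDate": "SHIFT_DATE",
    "SeriesDate": "SHIFT_DATE",
    "AcquisitionDate": "SHIFT_DATE",
    "ContentDate": "SHIFT_DATE",
    "StudyTime": "KEEP",
    "StudyID": "HASH_PSEUDONYM"
  },
  "uid_root": "2.25",
  "date_shift_range_days": 60,
  "default_clinical_action": "KEEP"
}
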