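<?xml version="1.0" encoding="UTF-8"?>
<!-- Synthetic variation-report fixture: constructed by hand to exercise the
     XML subset parser; not a real database record. -->
<ClinVarResult-Set>
  <VariationReport VariationID="424242" VariationType="Simple">
    <ClinicalSignificance>
      <ReviewStatus>criteria provided, multiple submitters, no conflicts</ReviewStatus>
      <Description>Pathogenic</Description>
      <DateLastEvaluated>2018-01-02</DateLastEvaluated>
    </ClinicalSignificance>
    <Allele AlleleID="100001">
      <AltAllele>T</AltAllele>
      <XRefList>
        <XRef DB="dbSNP" ID="199400001" Type="rs"/>
      </XRefList>
    </Allele>
    <TraitSet>
      <Trait>
        <Name>Synthetic cardiomyopathy</Name>
      </Trait>
    </TraitSet>
    <ClinicalAssertionList>
      <ClinicalAssertion SubmitterName="lab one">
        <ReviewStatus>criteria provided, single submitter</ReviewStatus>
        <ClinicalSignificance>
          <Description>Pathogenic</Description>
          <DateLastEvaluated>2014-10-07</DateLastEvaluated>
        </ClinicalSignificance>
      </ClinicalAssertion>
      <ClinicalAssertion SubmitterName="lab two">
        <ReviewStatus>criteria provided, single submitter</ReviewStatus>
        <ClinicalSignificance>
          <Description>Pathogenic</Description>
          <DateLastEvaluated>2018-01-02</DateLastEvaluated>
        </ClinicalSignificance>
      </ClinicalAssertion>
      <ClinicalAssertion SubmitterName="legacy submitter">
        <ReviewStatus>no assertion criteria provided</ReviewStatus>
        <ClinicalSignificance>
          <Description>Uncertain significance</Description>
        </ClinicalSignificance>
      </ClinicalAssertion>
    </ClinicalAssertionList>
  </VariationReport>
</ClinVarResult-Set>
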