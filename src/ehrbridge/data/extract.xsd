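<?xml version="1.0" encoding="UTF-8"?>
<!-- EHR extract dialect: a namespaced subset of the EN/ISO 13606 extract
     structure (extract -> entries -> elements with typed value nodes). -->
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema"
           targetNamespace="urn:ehrbridge:extract:1"
           xmlns:e="urn:ehrbridge:extract:1"
           elementFormDefault="qualified"
           attributeFormDefault="unqualified">

  <xs:element name="extract">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="provenance">
          <xs:complexType>
            <xs:attribute name="source" type="xs:string" use="required"/>
            <xs:attribute name="extracted-at" type="xs:dateTime" use="required"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="entry" minOccurs="0" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="element" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:choice>
                    <xs:element name="coded-text">
                      <xs:complexType>
                        <xs:attribute name="code" type="xs:string" use="required"/>
                        <xs:attribute name="code-system" use="required">
                          <xs:simpleType>
                            <xs:restriction base="xs:string">
                              <xs:minLength value="1"/>
                            </xs:restriction>
                          </xs:simpleType>
                        </xs:attribute>
                        <xs:attribute name="display" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="simple-text" type="xs:string"/>
                    <xs:element name="date-time">
                      <xs:complexType>
                        <xs:attribute name="value" type="xs:dateTime" use="required"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="quantity">
                      <xs:complexType>
                        <xs:attribute name="magnitude" type="xs:decimal" use="required"/>
                        <xs:attribute name="units" use="required">
                          <xs:simpleType>
                            <xs:restriction base="xs:string">
                              <xs:minLength value="1"/>
                            </xs:restriction>
                          </xs:simpleType>
                        </xs:attribute>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="identifier">
                      <xs:complexType>
                        <xs:attribute name="value" type="xs:string" use="required"/>
                        <xs:attribute name="scope" type="xs:string"/>
                      </xs:complexType>
                    </xs:element>
                    <xs:element name="boolean">
                      <xs:complexType>
                        <xs:attribute name="value" type="xs:boolean" use="required"/>
                      </xs:complexType>
                    </xs:element>
                  </xs:choice>
                  <xs:attribute name="node_id" type="xs:string" use="required"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="archetype_id" type="xs:string" use="required"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="extract_id" type="xs:string" use="required"/>
      <xs:attribute name="patient_id" type="xs:string" use="required"/>
    </xs:complexType>
  </xs:element>

</xs:schema>
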